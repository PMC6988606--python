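"""Exception hierarchy.

Three top-level families map onto distinct CLI exit codes: usage errors
(bad invocation), domain errors (bad state or arguments at the library
level), and transport errors (network failures and integrity violations).
"""

from __future__ import annotations


class RefAssetsError(Exception):
    """Base class for all domain-level errors raised by this package."""


class RegistryPathError(RefAssetsError, ValueError):
    """A registry path string could not be parsed."""


class ConfigError(RefAssetsError):
    """Genome configuration file is missing, malformed, or inconsistent."""


class ConfigVersionError(ConfigError):
    """Configuration file declares an unsupported config_version."""


class MissingEntryError(RefAssetsError, KeyError):
    """A genome / asset / tag / seek-key lookup failed.

    ``level`` names the first level of the hierarchy that was absent, so
    callers (and API responses) can distinguish an unknown genome from an
    unknown tag of a known asset.
    """

    def __init__(self, message: str, level: str):
        super().__init__(message)
        self.level = level

    def __str__(self) -> str:  # KeyError quotes its arg; keep plain text
        return self.args[0]


class RecipeError(RefAssetsError):
    """A recipe is unknown or its declaration is internally inconsistent."""


class BuildError(RefAssetsError):
    """An asset build failed; no partial output was registered."""


class NetworkError(RefAssetsError):
    """All attempts to reach remote servers failed."""


class IntegrityError(RefAssetsError):
    """Downloaded or on-disk content does not match its recorded digest."""
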