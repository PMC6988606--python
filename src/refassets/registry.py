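"""Asset registry paths: parse and format ``genome/asset[.seek_key][:tag]``.

A registry path is the human-readable identifier used throughout the
package to address one tagged version of one genome asset, optionally
narrowed to a single file inside it via a seek-key suffix.  Tokens are
restricted to ``[A-Za-z0-9_-]`` because every component becomes a
filesystem path component verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .exceptions import RegistryPathError

DEFAULT_TAG = "default"

TOKEN_RE = re.compile(r"[A-Za-z0-9_-]+")

_PATH_RE = re.compile(
    r"^(?P<genome>[A-Za-z0-9_-]+)"
    r"/(?P<asset>[A-Za-z0-9_-]+)"
    r"(?:\.(?P<seek_key>[A-Za-z0-9_-]+))?"
    r"(?::(?P<tag>[A-Za-z0-9_-]+))?$"
)


def is_token(s: str) -> bool:
    """True if *s* is a legal genome/asset/tag/seek-key token."""
    return bool(TOKEN_RE.fullmatch(s))


@dataclass(frozen=True)
class AssetRegistryPath:
    """Parsed form of a registry path.

    ``tag`` is never empty: an absent tag means the literal tag name
    ``default``.  ``seek_key`` is ``None`` unless the path carried a
    ``.seek_key`` suffix on the asset component.
    """

    genome: str
    asset: str
    tag: str = DEFAULT_TAG
    seek_key: Optional[str] = None

    def __post_init__(self) -> None:
        for field_name in ("genome", "asset", "tag"):
            value = getattr(self, field_name)
            if not is_token(value):
                raise RegistryPathError(
                    f"invalid {field_name} token {value!r}: allowed characters "
                    "are letters, digits, '_' and '-'"
                )
        if self.seek_key is not None and not is_token(self.seek_key):
            raise RegistryPathError(f"invalid seek_key token {self.seek_key!r}")

    def with_seek_key(self, seek_key: Optional[str]) -> "AssetRegistryPath":
        return AssetRegistryPath(self.genome, self.asset, self.tag, seek_key)

    def __str__(self) -> str:
        return format_registry_path(self)


def parse_registry_path(s: str) -> AssetRegistryPath:
    """Parse a registry path string.

    Grammar: ``genome/asset[.seek_key][:tag]``.  A missing tag is filled
    with ``default``; a missing seek key is left unset.

    Raises
    ------
    RegistryPathError
        For empty input, a missing ``/``, empty components, repeated
        separators, or characters outside the token alphabet.  The error
        message names the offending string.
    """
    if not isinstance(s, str) or not s:
        raise RegistryPathError("empty registry path")
    m = _PATH_RE.fullmatch(s)
    if m is None:
        raise RegistryPathError(
            f"malformed registry path {s!r}: expected genome/asset[.seek_key][:tag] "
            "with tokens of letters, digits, '_' and '-'"
        )
    return AssetRegistryPath(
        genome=m.group("genome"),
        asset=m.group("asset"),
        tag=m.group("tag") or DEFAULT_TAG,
        seek_key=m.group("seek_key"),
    )


def format_registry_path(p: AssetRegistryPath) -> str:
    """Render *p* canonically as ``genome/asset[.seek_key]:tag``.

    ``parse_registry_path(format_registry_path(p)) == p`` for every valid
    path, and formatting a parsed string yields its canonical form (the
    tag always spelled out).
    """
    seek = f".{p.seek_key}" if p.seek_key else ""
    return f"{p.genome}/{p.asset}{seek}:{p.tag}"
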