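"""Layered ("superposed") INI configuration.

Configuration files are read in the user-given order and merged key by key,
later files overwriting earlier ones. Lookups consult the requested section
first and fall back to ``[DEFAULT]``. Values are literal strings — there is
no interpolation — which keeps rendered commands, and hence their digests,
stable and auditable. The fully merged effective configuration can be
written back out as a trace INI for reproducibility; reloading the trace as
the sole configuration yields an identical parameter set.

Section and key names are case-sensitive. If the same key appears twice in
one file, the last occurrence in that file wins (standard INI reading).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError, FormatError

DEFAULT_SECTION = "DEFAULT"

#: Sentinel configparser default-section name so that a literal ``[DEFAULT]``
#: section in user files is treated as an ordinary section and the engine's
#: own fallback rule (section, then DEFAULT) is the only one in force.
_UNUSED_DEFAULT = "@@genflow-unused-default@@"

_ABSENT = object()

PARAM_TYPES = ("string", "int", "float", "path", "list")


@dataclass
class ConfigStore:
    """Merged configuration with per-key provenance.

    ``provenance`` maps ``(section, key)`` to the index (into
    ``source_files``) of the file that last set the key.
    """

    sections: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], int] = field(default_factory=dict)
    source_files: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sections.setdefault(DEFAULT_SECTION, {})

    def raw_get(self, section: str, key: str):
        """Lookup with DEFAULT fallback; returns the raw string or the
        module-level absent sentinel."""
        sect = self.sections.get(section, {})
        if key in sect:
            return sect[key]
        return self.sections[DEFAULT_SECTION].get(key, _ABSENT)

    def get(
        self,
        section: str,
        key: str,
        required: bool = False,
        param_type: str = "string",
        default=None,
    ):
        return get_param(self, section, key, required, param_type, default)


def _read_ini(path: Path) -> configparser.ConfigParser:
    parser = configparser.ConfigParser(
        interpolation=None,
        default_section=_UNUSED_DEFAULT,
        strict=False,
        delimiters=("=",),
    )
    parser.optionxform = str  # case-sensitive keys
    try:
        with open(path) as handle:
            parser.read_file(handle, source=str(path))
    except OSError as exc:
        raise ConfigError(f"cannot read configuration file {path}: {exc}") from exc
    except configparser.Error as exc:
        raise FormatError(f"INI syntax error: {exc}") from exc
    return parser


def load_config(paths: list[str | Path]) -> ConfigStore:
    """Read INI files in order into a single last-wins merged store."""
    if not paths:
        raise ConfigError("at least one configuration file is required")
    store = ConfigStore()
    for index, raw_path in enumerate(paths):
        path = Path(raw_path)
        store.source_files.append(str(path))
        parser = _read_ini(path)
        for section in parser.sections():
            target = store.sections.setdefault(section, {})
            for key, value in parser.items(section):
                target[key] = value
                store.provenance[(section, key)] = index
    return store


def _coerce(raw: str, param_type: str, section: str, key: str):
    if param_type == "string":
        return raw
    if param_type == "int":
        try:
            return int(raw)
        except ValueError:
            raise ConfigError(
                f"[{section}] {key}: cannot coerce {raw!r} to int"
            ) from None
    if param_type == "float":
        try:
            return float(raw)
        except ValueError:
            raise ConfigError(
                f"[{section}] {key}: cannot coerce {raw!r} to float"
            ) from None
    if param_type == "path":
        return str(Path(raw))
    if param_type == "list":
        return [item.strip() for item in raw.split(",") if item.strip()]
    raise ConfigError(
        f"unknown parameter type {param_type!r}; expected one of {PARAM_TYPES}"
    )


def get_param(
    store: ConfigStore,
    section: str,
    key: str,
    required: bool = False,
    param_type: str = "string",
    default=None,
):
    """Typed lookup: ``[section]`` first, then ``[DEFAULT]``.

    Returns ``default`` (``None`` unless given) when the key is absent and
    not required. ``list`` values are comma-split and whitespace-trimmed.
    No file I/O happens here; everything was read at load time.
    """
    raw = store.raw_get(section, key)
    if raw is _ABSENT:
        if required:
            searched = ", ".join(store.source_files) or "<none>"
            raise ConfigError(
                f"required parameter [{section}] {key} not found "
                f"(searched [{section}] and [DEFAULT] in: {searched})"
            )
        return default
    return _coerce(raw, param_type, section, key)


def write_trace(store: ConfigStore, path: str | Path) -> None:
    """Write the fully merged effective configuration as a sorted INI file.

    Empty non-DEFAULT sections are omitted. Reloading the trace as the sole
    configuration file reproduces the store's section/key/value content.
    """
    path = Path(path)
    lines: list[str] = [
        "# genflow effective configuration trace",
        "# merged from, in order:",
    ]
    for source in store.source_files:
        lines.append(f"#   {source}")
    section_names = sorted(store.sections)
    # DEFAULT first so fallback keys are visible at the top
    if DEFAULT_SECTION in section_names:
        section_names.remove(DEFAULT_SECTION)
        section_names.insert(0, DEFAULT_SECTION)
    for section in section_names:
        items = store.sections[section]
        if not items and section != DEFAULT_SECTION:
            continue
        lines.append("")
        lines.append(f"[{section}]")
        for key in sorted(items):
            lines.append(f"{key}={items[key]}")
    lines.append("")
    try:
        path.write_text("\n".join(lines))
    except OSError as exc:
        raise ConfigError(f"cannot write trace file {path}: {exc}") from exc
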