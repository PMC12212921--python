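"""Single-source configuration and intermediate-file validation.

All shared parameters — directory layout, expected file headers, plate
formats and scan orders, batch sizes, band-size thresholds, barcode prefixes
— live in one declarative TOML file, so a change is made in exactly one
place.  Keys may be defined only once (a duplicate definition is an error
naming the key), and paths are resolved relative to an invocation root so
the pipeline runs unchanged wherever the directory tree is mounted.
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .errors import ConfigError

__all__ = [
    "Config",
    "load_config",
    "default_config",
    "ValidationReport",
    "validate_intermediate",
]

_KEY_RE = re.compile(r'^\s*([A-Za-z0-9_"\'.-]+)\s*=')
_SECTION_RE = re.compile(r"^\s*\[+([^\]]+)\]+\s*$")


def _scan_duplicate_keys(text: str) -> None:
    """Reject a TOML document in which any key is assigned twice.

    The scan is line-based (sufficient for the flat key=value style this
    config uses) and names the offending key and section.
    """
    section = ""
    seen: set[tuple[str, str]] = set()
    for line in text.splitlines():
        stripped = line.split("#", 1)[0]
        m = _SECTION_RE.match(stripped)
        if m:
            section = m.group(1).strip()
            continue
        m = _KEY_RE.match(stripped)
        if m:
            key = m.group(1).strip("\"'")
            if (section, key) in seen:
                where = f"[{section}] " if section else ""
                raise ConfigError(f"duplicate configuration key {where}{key!r}")
            seen.add((section, key))


@dataclass
class Config:
    """Parsed configuration with root-resolved paths."""

    data: dict[str, Any]
    root: Path
    source: Path | None = None

    def __getitem__(self, dotted: str) -> Any:
        node: Any = self.data
        for part in dotted.split("."):
            if not isinstance(node, Mapping) or part not in node:
                raise ConfigError(f"missing configuration key {dotted!r}")
            node = node[part]
        return node

    def get(self, dotted: str, default: Any = None) -> Any:
        try:
            return self[dotted]
        except ConfigError:
            return default

    def path(self, dotted: str) -> Path:
        """A [paths] entry resolved against the invocation root."""
        return self.root / str(self[dotted])

    def step(self, name: str) -> dict[str, Any]:
        steps = self.data.get("steps", {})
        if name not in steps:
            raise ConfigError(
                f"unknown step {name!r}; configured steps: {sorted(steps)}"
            )
        return steps[name]

    def step_out_dir(self, name: str) -> Path:
        """Numbered output directory of a step (NN_<STEP>_Out under root)."""
        step = self.step(name)
        return self.root / f"{int(step['number']):02d}_{name.upper()}_Out"

    def header(self, kind: str) -> list[str]:
        return list(self["headers." + kind])


def load_config(path: str | Path, root: str | Path | None = None) -> Config:
    """Load a configuration file, rejecting duplicate key definitions.

    ``root`` (default: the file's directory) anchors every relative path, so
    relocating the whole working tree requires no config edits.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    _scan_duplicate_keys(text)
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path.name}: {exc}") from exc
    return Config(data=data, root=Path(root) if root is not None else path.parent, source=path)


def default_config(root: str | Path | None = None) -> Config:
    """The packaged default configuration (root defaults to the CWD)."""
    with resources.as_file(resources.files("mabflow") / "data" / "default_config.toml") as p:
        cfg = load_config(p)
    cfg.root = Path(root) if root is not None else Path.cwd()
    return cfg


@dataclass(frozen=True)
class Violation:
    kind: str  # header | type | count
    message: str


@dataclass
class ValidationReport:
    """Outcome of validating one intermediate file; empty means clean."""

    path: Path
    violations: list[Violation] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)

    def summary(self) -> str:
        if self.is_clean:
            return f"{self.path.name}: OK"
        lines = [f"{self.path.name}: {len(self.violations)} problem(s)"]
        lines += [f"  [{v.kind}] {v.message}" for v in self.violations]
        return "\n".join(lines)


def validate_intermediate(
    path: str | Path,
    expected_columns: Sequence[str],
    expected_count: int | None = None,
    column_types: Mapping[str, type] | None = None,
) -> ValidationReport:
    """Validate an intermediate file against its configured contract.

    Checks the header (exact column names and order), optionally the number
    of data rows against the declared expectation, and optionally that given
    columns parse as a type.  Returns a report rather than raising, so
    callers decide whether a violation aborts the run.
    """
    path = Path(path)
    report = ValidationReport(path=path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        report.violations.append(Violation("header", f"unreadable file: {exc}"))
        return report
    header = list(df.columns)
    if header != list(expected_columns):
        missing = [c for c in expected_columns if c not in header]
        extra = [c for c in header if c not in expected_columns]
        for c in missing:
            report.violations.append(Violation("header", f"missing column {c!r}"))
        for c in extra:
            report.violations.append(Violation("header", f"unexpected column {c!r}"))
        if not missing and not extra:
            report.violations.append(
                Violation("header", f"column order {header} != expected {list(expected_columns)}")
            )
    if expected_count is not None and len(df) != expected_count:
        report.violations.append(
            Violation("count", f"{len(df)} rows found, {expected_count} expected")
        )
    for col, typ in (column_types or {}).items():
        if col not in df.columns:
            continue
        for i, raw in enumerate(df[col]):
            try:
                typ(raw)
            except (TypeError, ValueError):
                report.violations.append(
                    Violation("type", f"line {i + 2}: {col}={raw!r} is not {typ.__name__}")
                )
    return report
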