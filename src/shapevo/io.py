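"""Readers and writers: UCR-style delimited text, shapelet-set JSON,
distance-matrix TSV, flat config files, and line-delimited evolution logs.

The UCR convention is one series per row, class label in the first column,
values in the remaining columns; rows may have different lengths. Labels
(integer or string) are mapped to contiguous integers in first-appearance
order internally and restored on output. Shapelet sets round-trip through
JSON bit-exactly (Python's float repr is shortest-exact).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .core import MIN_SHAPELET_LEN, Shapelet, ShapeletSet, TimeSeriesDataset
from .engine import EvolutionConfig, EvolutionLog

FORMAT_VERSION = 1


class ParseError(ValueError):
    pass


def read_ucr_tsv(path, delimiter: str = "\t") -> TimeSeriesDataset:
    """Parse a UCR-style delimited file into a dataset.

    Rows with fewer than MIN_SHAPELET_LEN values are rejected; non-numeric
    values raise a ParseError naming the row and column (1-based).
    """
    series, labels = [], []
    with open(path) as fh:
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f for f in line.split(delimiter) if f != ""]
            if len(fields) - 1 < MIN_SHAPELET_LEN:
                raise ParseError(
                    f"row {row_no}: series has {len(fields) - 1} values, "
                    f"need at least {MIN_SHAPELET_LEN}"
                )
            label = fields[0]
            try:
                label = int(label)
            except ValueError:
                pass  # keep string labels
            values = []
            for col_no, field in enumerate(fields[1:], start=2):
                try:
                    values.append(float(field))
                except ValueError:
                    raise ParseError(
                        f"row {row_no}, column {col_no}: "
                        f"non-numeric value {field!r}"
                    ) from None
            labels.append(label)
            series.append(np.asarray(values))
    if not series:
        raise ParseError(f"{path}: no series found")
    return TimeSeriesDataset(series, labels)


def write_ucr_tsv(dataset: TimeSeriesDataset, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for t, lab in zip(dataset.series, dataset.labels):
            original = dataset.label_names[lab]
            fh.write(delimiter.join([str(original)] + [repr(float(v)) for v in t]))
            fh.write("\n")


# ------------------------------------------------------------ shapelet JSON

def _config_snapshot(config: Optional[EvolutionConfig]) -> Optional[dict]:
    if config is None:
        return None
    return dataclasses.asdict(config)


def write_shapelet_set(
    shapelet_set: ShapeletSet,
    path,
    config: Optional[EvolutionConfig] = None,
    seed: Optional[int] = None,
    provenance: Optional[list] = None,
) -> None:
    """Serialize a shapelet set with its config snapshot and fitness.

    ``provenance`` entries, when given, are per-shapelet: either the string
    "evolved" or a (series_index, start) pair in 0-based half-open
    coordinates.
    """
    doc = {
        "format_version": FORMAT_VERSION,
        "shapelets": [
            {
                "values": [float(v) for v in s.values],
                "provenance": provenance[i] if provenance else "evolved",
            }
            for i, s in enumerate(shapelet_set)
        ],
        "config": _config_snapshot(config),
        "fitness": (
            None
            if shapelet_set.fitness is None
            else {
                "error": shapelet_set.fitness.error,
                "complexity": shapelet_set.fitness.complexity,
            }
        ),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_shapelet_set(path) -> ShapeletSet:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed shapelet document: {exc}") from None
    if not isinstance(doc, dict) or "format_version" not in doc:
        raise ParseError(f"{path}: missing format_version field")
    if doc["format_version"] != FORMAT_VERSION:
        raise ParseError(
            f"{path}: unsupported format version {doc['format_version']!r} "
            f"(expected {FORMAT_VERSION})"
        )
    try:
        shapelets = [Shapelet(np.asarray(s["values"], dtype=float)) for s in doc["shapelets"]]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed shapelet entry: {exc}") from None
    return ShapeletSet(shapelets)


# ----------------------------------------------------------- other formats

def write_distance_matrix(D: np.ndarray, path, delimiter: str = "\t") -> None:
    np.savetxt(path, np.asarray(D), delimiter=delimiter, fmt="%.17g")


def read_distance_matrix(path, delimiter: str = "\t") -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=delimiter))


def config_to_text(config: EvolutionConfig, path) -> None:
    """Flat key=value serialization of the evolution hyper-parameters."""
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = ",".join(value)
        lines.append(f"{f.name}={value}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_from_text(path) -> EvolutionConfig:
    kwargs: dict = {}
    field_types = {f.name: f for f in dataclasses.fields(EvolutionConfig)}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"line {line_no}: expected key=value, got {line!r}")
        key, raw = line.split("=", 1)
        key, raw = key.strip(), raw.strip()
        if key not in field_types:
            raise ParseError(f"line {line_no}: unknown key {key!r}")
        if key.startswith("enabled_"):
            kwargs[key] = tuple(x for x in raw.split(",") if x)
        elif raw == "None":
            kwargs[key] = None
        elif key.startswith("p_"):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = int(raw)
    return EvolutionConfig(**kwargs)


def write_evolution_log(log: EvolutionLog, path) -> None:
    """Line-delimited JSON records, one generation per line, followed by a
    terminal record carrying the stopping reason."""
    with open(path, "w") as fh:
        for r in log.records:
            fh.write(json.dumps(dataclasses.asdict(r)) + "\n")
        fh.write(json.dumps({"stopping_reason": log.stopping_reason}) + "\n")
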