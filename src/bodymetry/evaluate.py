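"""Error statistics, method comparison and longitudinal change reports.

Percent errors are aggregated as a root-mean-square, ``sqrt(mean(e^2))``,
the convention used by the reference validation study this package
reproduces; the plain arithmetic mean is reported alongside for
transparency.  Errors are computed on unrounded values and rounded to two
decimals only for display.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from bodymetry.errors import ValidationError
from bodymetry.measure import BodyMeasurements

__all__ = [
    "ErrorRecord",
    "ErrorSummary",
    "MethodComparison",
    "ChangeReport",
    "percent_error",
    "rms_average",
    "summarize",
    "summarize_csv",
    "compare_values",
    "compare_methods",
    "monitor_change",
]


def percent_error(actual: float, measured: float) -> float:
    """Absolute percent error ``|actual - measured| / actual * 100``."""
    if actual <= 0:
        raise ValidationError(f"actual must be positive, got {actual}")
    if measured < 0:
        raise ValidationError(f"measured must be non-negative, got {measured}")
    return abs(actual - measured) / actual * 100.0


def rms_average(errors: Sequence[float]) -> float:
    """Root-mean-square of percent errors: ``sqrt(mean(e^2))``.

    Always >= the arithmetic mean, with equality iff all entries agree.
    """
    e = np.asarray(list(errors), dtype=float)
    if e.size == 0:
        raise ValidationError("cannot aggregate an empty error list")
    if np.any(e < 0):
        raise ValidationError("percent errors must be non-negative")
    return float(np.sqrt(np.mean(e * e)))


@dataclass(frozen=True)
class ErrorRecord:
    label: str
    actual_cm: float
    measured_cm: float
    percent: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "percent", percent_error(self.actual_cm, self.measured_cm))


@dataclass
class ErrorSummary:
    records: list[ErrorRecord]

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def rms_percent(self) -> float:
        return rms_average([r.percent for r in self.records])

    @property
    def mean_percent(self) -> float:
        return float(np.mean([r.percent for r in self.records]))

    def to_json(self, path=None) -> str:
        payload = {
            "n": self.n,
            "rms_percent": round(self.rms_percent, 2),
            "mean_percent": round(self.mean_percent, 2),
            "records": [
                {
                    "label": r.label,
                    "actual_cm": r.actual_cm,
                    "measured_cm": r.measured_cm,
                    "percent_error": round(r.percent, 2),
                }
                for r in self.records
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            "| label | actual (cm) | measured (cm) | error (%) |",
            "|---|---|---|---|",
        ]
        for r in self.records:
            lines.append(
                f"| {r.label} | {r.actual_cm:.2f} | {r.measured_cm:.2f} | {r.percent:.2f} |"
            )
        lines.append(
            f"\nRMS error: {self.rms_percent:.2f}% over {self.n} records "
            f"(plain mean {self.mean_percent:.2f}%)."
        )
        return "\n".join(lines)


def summarize(records: Sequence[ErrorRecord]) -> ErrorSummary:
    if not records:
        raise ValidationError("no error records to summarize")
    return ErrorSummary(list(records))


def summarize_csv(path) -> ErrorSummary:
    """Summarize a CSV of (label, actual, measured) rows."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        lab, act, mea = cols["label"], cols["actual"], cols["measured"]
    except KeyError as exc:
        raise ValidationError(f"CSV must have label/actual/measured columns: {exc}")
    if df.empty:
        raise ValidationError(f"no rows in {path}")
    return summarize(
        [ErrorRecord(str(r[lab]), float(r[act]), float(r[mea])) for _, r in df.iterrows()]
    )


# ---------------------------------------------------------------------------
# method comparison


@dataclass
class MethodComparison:
    """Per-landmark actual/cosine/ellipse values with errors and winner."""

    rows: dict[str, dict[str, float]]  # landmark -> numbers
    closer: dict[str, str]  # landmark -> "cosine" | "ellipse" | "tie"

    def to_markdown(self) -> str:
        lines = [
            "| landmark | actual | cosine | ellipse | cos err % | ell err % | closer |",
            "|---|---|---|---|---|---|---|",
        ]
        for lm, row in self.rows.items():
            lines.append(
                f"| {lm} | {row['actual']:.2f} | {row['cosine']:.2f} | "
                f"{row['ellipse']:.2f} | {row['cosine_error_pct']:.2f} | "
                f"{row['ellipse_error_pct']:.2f} | {self.closer[lm]} |"
            )
        return "\n".join(lines)


def compare_values(actual: float, cosine: float, ellipse: float) -> tuple[dict, str]:
    """Compare both estimators against one true circumference."""
    ce = percent_error(actual, cosine)
    ee = percent_error(actual, ellipse)
    if math.isclose(ce, ee, rel_tol=0.0, abs_tol=1e-12):
        closer = "tie"
    else:
        closer = "cosine" if ce < ee else "ellipse"
    row = {
        "actual": actual,
        "cosine": cosine,
        "ellipse": ellipse,
        "cosine_error_pct": ce,
        "ellipse_error_pct": ee,
    }
    return row, closer


def compare_methods(
    measurements: BodyMeasurements, truth: dict[str, float]
) -> MethodComparison:
    """Cosine-vs-ellipse comparison at the waist and hip landmarks.

    ``truth`` maps landmark name (``waist``/``hip``) to the actual
    circumference in cm.
    """
    rows, closer = {}, {}
    for landmark, values in (("waist", measurements.waist_cm), ("hip", measurements.hip_cm)):
        if landmark not in truth:
            continue
        if "cosine" not in values or "ellipse" not in values:
            raise ValidationError(f"{landmark}: both method values are required")
        rows[landmark], closer[landmark] = compare_values(
            float(truth[landmark]), values["cosine"], values["ellipse"]
        )
    if not rows:
        raise ValidationError("truth must provide 'waist' and/or 'hip'")
    return MethodComparison(rows, closer)


# ---------------------------------------------------------------------------
# change monitoring


@dataclass
class ChangeReport:
    """Old-vs-new landmark deltas; negative deltas mean slimming."""

    old: BodyMeasurements
    new: BodyMeasurements
    delta_cm: dict[str, dict[str, float]] = field(init=False)
    delta_percent: dict[str, dict[str, float]] = field(init=False)

    def __post_init__(self):
        self.delta_cm = {}
        self.delta_percent = {}
        for lm, old_v, new_v in (
            ("waist", self.old.waist_cm, self.new.waist_cm),
            ("hip", self.old.hip_cm, self.new.hip_cm),
        ):
            self.delta_cm[lm] = {m: new_v[m] - old_v[m] for m in old_v if m in new_v}
            self.delta_percent[lm] = {
                m: (new_v[m] - old_v[m]) / old_v[m] * 100.0
                for m in old_v
                if m in new_v and old_v[m] > 0
            }

    def to_json(self, path=None) -> str:
        payload = {
            "delta_cm": {
                lm: {m: round(v, 2) for m, v in d.items()} for lm, d in self.delta_cm.items()
            },
            "delta_percent": {
                lm: {m: round(v, 2) for m, v in d.items()}
                for lm, d in self.delta_percent.items()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def monitor_change(old: BodyMeasurements, new: BodyMeasurements) -> ChangeReport:
    """Compare two measurement sessions of the same subject.

    Both sessions must share the landmark configuration (bands and row
    count), otherwise the deltas would not be like-for-like.
    """
    oc, nc = old.config, new.config
    if (oc.n_rows, oc.waist_band, oc.hip_band) != (nc.n_rows, nc.waist_band, nc.hip_band):
        raise ValidationError(
            "configuration mismatch between sessions: "
            f"{(oc.n_rows, oc.waist_band, oc.hip_band)} vs "
            f"{(nc.n_rows, nc.waist_band, nc.hip_band)}"
        )
    return ChangeReport(old=old, new=new)
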