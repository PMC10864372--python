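"""Ca²⁺-uptake table arithmetic and model-vs-experiment comparison.

The experimental record is a table of cytoplasmic Ca²⁺ readings (percent
of an ionophore-saturated maximum) at increasing NMDA concentration, for
a control culture and one exposed to a 100 mT static field.  The
field/control ratio per row, and its mean over rows, quantify the
magnitude of the field effect.  The model's singlet-yield ratio S is
compared to these magnitudes only — the biochemical cascade between
radical-pair singlet yield and Ca²⁺ influx is not modelled, and an
amplification between the two scales is expected.

The shipped tables are approximate values extracted from published
plots; both the percentage columns and the published ratio column are
rounded to one decimal, so recomputed ratios are checked for
*consistency at the printed precision* (see
:func:`ratio_consistent_with_printed`) rather than exact equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CaUptakeTable",
    "load_table",
    "load_published_tables",
    "compute_ratios",
    "round_half_up",
    "ratio_consistent_with_printed",
    "average_factor",
    "compare_model_to_experiment",
]

REQUIRED_COLUMNS = ("nmda_um", "control_pct", "field_pct")


@dataclass(frozen=True)
class CaUptakeTable:
    """One exposure experiment's Ca²⁺-uptake measurements."""

    exposure: str  # "sustained" | "repeated" | custom label
    data: pd.DataFrame  # columns nmda_um, control_pct, field_pct [, printed_ratio]
    source: str = ""

    def __post_init__(self):
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"table is missing columns {missing}")
        if len(df) < 1:
            raise ValueError("table must have at least one row")
        for col in ("control_pct", "field_pct"):
            if not ((df[col] > 0) & (df[col] <= 100)).all():
                raise ValueError(f"{col} must lie in (0, 100]")
        if not df["nmda_um"].is_monotonic_increasing or df["nmda_um"].duplicated().any():
            raise ValueError("NMDA concentrations must be strictly increasing")

    @property
    def printed_ratios(self) -> np.ndarray | None:
        if "printed_ratio" in self.data.columns:
            return self.data["printed_ratio"].to_numpy(float)
        return None


def load_table(path_or_buffer, exposure: str = "custom", source: str = "") -> CaUptakeTable:
    """Read a CaUptakeTable from CSV ('#' lines are provenance comments)."""
    df = pd.read_csv(path_or_buffer, comment="#")
    return CaUptakeTable(exposure=exposure, data=df, source=source)


def load_published_tables() -> dict[str, CaUptakeTable]:
    """The two shipped exposure tables, keyed 'sustained' and 'repeated'."""
    out = {}
    for key in ("sustained", "repeated"):
        ref = resources.files("rpmspin.data") / f"table_{key}.csv"
        with ref.open() as fh:
            out[key] = load_table(fh, exposure=key, source=f"table_{key}.csv")
    return out


def round_half_up(x, decimals: int = 1):
    """Decimal round-half-up (the convention of the printed ratio column)."""
    q = Decimal(10) ** -decimals
    if np.ndim(x) == 0:
        return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return np.array([round_half_up(v, decimals) for v in np.asarray(x).ravel()])


def compute_ratios(table: CaUptakeTable, rounded: bool = False) -> np.ndarray:
    """Per-row field/control uptake ratios.

    With ``rounded=True`` the ratios are rounded half-up to one decimal
    for comparison against a published 1-d.p. ratio column.
    """
    control = table.data["control_pct"].to_numpy(float)
    field = table.data["field_pct"].to_numpy(float)
    if np.any(control <= 0):
        raise ValueError("control percentages must be positive")
    ratios = field / control
    return round_half_up(ratios, 1) if rounded else ratios


def ratio_consistent_with_printed(table: CaUptakeTable, half_ulp: float = 0.05) -> np.ndarray:
    """Per-row check that the published ratio fits the published percentages.

    Both the percentage columns and the published ratio are rounded to
    one decimal, so the published ratio cell is accepted when it can be
    obtained as round(field/control, 1 d.p.) for *some* true values
    within ±``half_ulp`` of the printed percentages — i.e. when the
    rounding interval of the quotient contains the printed ratio.
    """
    printed = table.printed_ratios
    if printed is None:
        raise ValueError("table carries no printed_ratio column to compare against")
    control = table.data["control_pct"].to_numpy(float)
    field = table.data["field_pct"].to_numpy(float)
    lo = (field - half_ulp) / (control + half_ulp)
    hi = (field + half_ulp) / (control - half_ulp)
    ok = []
    for lo_i, hi_i, r_i in zip(lo, hi, printed):
        # attainable 1-d.p. roundings of any quotient in [lo_i, hi_i]
        attainable = np.arange(np.floor(lo_i * 10 + 0.5), np.floor(hi_i * 10 + 0.5) + 1) / 10
        ok.append(bool(np.any(np.isclose(attainable, r_i, atol=1e-9))))
    return np.array(ok)


def average_factor(table: CaUptakeTable) -> dict:
    """Mean per-row uptake ratio, unrounded and at the printed precision."""
    ratios = compute_ratios(table)
    mean = float(np.mean(ratios))
    return {"mean": mean, "mean_1dp": round_half_up(mean, 1)}


def compare_model_to_experiment(S: float, table: CaUptakeTable) -> dict:
    """Magnitude comparison of the model yield ratio S to the Ca²⁺ ratios.

    This is explicitly *not a fit*: downstream biochemical amplification
    between singlet yield and Ca²⁺ influx is acknowledged, so the report
    states magnitudes side by side and whether S falls inside the range
    the rows span.
    """
    if S <= 0:
        raise ValueError("model ratio S must be positive")
    ratios = compute_ratios(table)
    mean = float(np.mean(ratios))
    # the range check is at the precision the record is stated in: the
    # published 1-d.p. ratio column when present, else the quotients
    span = table.printed_ratios if table.printed_ratios is not None else ratios
    report = {
        "comparison": "magnitude comparison — not a fit",
        "exposure": table.exposure,
        "model_S": float(S),
        "row_ratios": [float(x) for x in ratios],
        "mean_ratio": mean,
        "mean_ratio_1dp": round_half_up(mean, 1),
        "S_over_mean": float(S) / mean,
        "S_within_row_range": bool(span.min() <= S <= span.max()),
    }
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
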