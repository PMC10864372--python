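"""Generators for every input the pipeline needs, with no downloads.

Three kinds of input are produced:

* the published constants of the two phosphorylation pathways (serine
  and tyrosine oxyradical radical pairs with hydrated-Mg⁺ partners),
  shipped as package data and surfaced as typed parameter objects;
* reproducible random radical-pair configurations for property tests;
* synthetic Ca²⁺-uptake tables with the same shape as the experimental
  records (saturating control curve, field enhancement declining with
  NMDA concentration, prescribed mean enhancement factor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment_compare import CaUptakeTable, load_published_tables
from .rp_model import Isotope, KineticsParams, RadicalPairParams

__all__ = [
    "PaperFixtures",
    "RandomRPSpec",
    "paper_fixtures",
    "pathway_params",
    "random_radical_pair",
    "synthetic_ca_table",
]

_SPIN_CHOICES = (0.0, 0.5, 1.0, 1.5, 2.5)


@dataclass(frozen=True)
class PaperFixtures:
    """The published constants bundle plus the two uptake tables."""

    ser: RadicalPairParams
    tyr: RadicalPairParams
    isotopes: tuple
    B0: float
    Bexp: float
    kinetics: KineticsParams
    g: float
    tables: dict


def _constants() -> dict:
    ref = resources.files("rpmspin.data") / "constants.json"
    with ref.open() as fh:
        return json.load(fh)


def pathway_params(name: str, B: float | None = None) -> RadicalPairParams:
    """Radical-pair parameters for pathway 'ser' or 'tyr'.

    The Mg nucleus fields are left spin-0 here; isotopologues are
    resolved by the isotope table at evaluation time.  ``B`` defaults to
    the control field.
    """
    c = _constants()
    key = name.lower()
    if key not in c["pathways"]:
        raise KeyError(f"unknown pathway {name!r}; expected one of {list(c['pathways'])}")
    p = c["pathways"][key]
    return RadicalPairParams(
        B=c["B0_mT"] if B is None else B,
        a_A=p["a_A_mT"],
        spin_A=p["spin_A"],
        g=c["g"],
        label=p["label"],
    )


def paper_fixtures(out_dir: str | Path | None = None) -> PaperFixtures:
    """The full published-input bundle; optionally written to ``out_dir``.

    When ``out_dir`` is given, the constants are written as JSON and the
    two uptake tables as CSV (same schema as the shipped package data).
    """
    c = _constants()
    isotopes = tuple(
        Isotope(row["weight"], row["spin"], row["a_mT"]) for row in c["isotope_table"]
    )
    fx = PaperFixtures(
        ser=pathway_params("ser"),
        tyr=pathway_params("tyr"),
        isotopes=isotopes,
        B0=c["B0_mT"],
        Bexp=c["Bexp_mT"],
        kinetics=KineticsParams(
            k=c["reference_kinetics"]["k_per_s"], r=c["reference_kinetics"]["r_per_s"]
        ),
        g=c["g"],
        tables=load_published_tables(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "constants.json", "w") as fh:
            json.dump(c, fh, indent=2)
        for key, table in fx.tables.items():
            table.data.to_csv(out / f"table_{key}.csv", index=False)
    return fx


@dataclass(frozen=True)
class RandomRPSpec:
    """Sampling ranges for random radical-pair configurations.

    One integer seed drives a single ``numpy.random.default_rng``
    source; identical seeds give identical draws.
    """

    seed: int
    spin_choices: tuple = _SPIN_CHOICES
    a_max_mT: float = 20.0
    B_max_mT: float = 200.0
    k_range: tuple = (1e4, 1e8)
    r_range: tuple = (1e4, 1e8)

    def __post_init__(self):
        if len(self.spin_choices) == 0:
            raise ValueError("spin_choices must be non-empty")
        for lo, hi in (self.k_range, self.r_range):
            if not (0 < lo <= hi < np.inf):
                raise ValueError("rate ranges must be positive and finite")
        if not (0 < self.a_max_mT < np.inf and 0 < self.B_max_mT < np.inf):
            raise ValueError("magnitude ranges must be positive and finite")


def random_radical_pair(spec: RandomRPSpec):
    """Reproducible random (RadicalPairParams, KineticsParams) draw.

    Spins are drawn uniformly from ``spin_choices``, hyperfine constants
    uniformly in ±``a_max_mT`` (signed), B uniformly in [0, B_max_mT],
    and rates log-uniformly over their ranges.
    """
    rng = np.random.default_rng(spec.seed)
    spin_A, spin_B = rng.choice(spec.spin_choices, size=2)
    a_A, a_B = rng.uniform(-spec.a_max_mT, spec.a_max_mT, size=2)
    B = rng.uniform(0.0, spec.B_max_mT)
    k = 10 ** rng.uniform(np.log10(spec.k_range[0]), np.log10(spec.k_range[1]))
    r = 10 ** rng.uniform(np.log10(spec.r_range[0]), np.log10(spec.r_range[1]))
    params = RadicalPairParams(
        B=B, a_A=a_A, spin_A=float(spin_A), a_B=a_B, spin_B=float(spin_B),
        label=f"random-{spec.seed}",
    )
    return params, KineticsParams(k=k, r=r)


def synthetic_ca_table(
    seed: int,
    n_rows: int = 5,
    amplification: float = 1.5,
    ratio_spread: float = 0.3,
    control_max_pct: float = 30.0,
    half_saturation_um: float = 5.0,
) -> CaUptakeTable:
    """Synthetic Ca²⁺-uptake table shaped like the experimental records.

    The control column follows a saturating response
    c(x) = control_max · x/(x + K) over log-spaced NMDA concentrations;
    the field column is the control scaled by per-row enhancement
    factors that decline linearly with row index (total drop
    ``ratio_spread``) and average exactly ``amplification``.  A small
    seeded jitter perturbs the control column only, so the prescribed
    mean ratio is preserved to machine precision.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be ≥ 1")
    if amplification <= 0:
        raise ValueError("amplification factor must be positive")
    rng = np.random.default_rng(seed)
    nmda = np.geomspace(1.0, 100.0, n_rows)
    control = control_max_pct * nmda / (nmda + half_saturation_um)
    control = control * (1 + rng.uniform(-0.05, 0.05, n_rows))
    if n_rows > 1:
        offsets = np.linspace(ratio_spread / 2, -ratio_spread / 2, n_rows)
    else:
        offsets = np.zeros(1)
    ratios = amplification + offsets
    field = control * ratios
    df = pd.DataFrame(
        {"nmda_um": nmda, "control_pct": control, "field_pct": field}
    )
    if np.any(field <= 0) or np.any(field > 100) or np.any(ratios <= 0):
        raise ValueError(
            "requested parameters push percentages outside (0, 100]; "
            "reduce amplification, spread or control_max_pct"
        )
    return CaUptakeTable(exposure="synthetic", data=df, source=f"synthetic(seed={seed})")
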