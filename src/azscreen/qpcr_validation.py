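"""qPCR-side mathematics of the validation arm.

Primer efficiency is estimated from a standard curve over a serial
dilution of pooled cDNA: quantification cycle (Cq) regressed on
log10(relative template amount); the amplification factor per cycle is
``E = 10 ** (-1 / slope)`` (E = 2 means perfect doubling).  Primers are
retained only when 1.8 <= E <= 2.0, boundaries inclusive.

The opposite-profile check formalizes the prediction used against a
non-shedding genotype: a gene genuinely required for abscission should
have an altered (much lower for up-regulated genes, much higher for
down-regulated genes) ripe-stage abundance in the abscission zone of
fruit that never shed, relative to its peak-normalized profile in
normally shedding fruit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .profile_tools import normalize_to_peak

__all__ = [
    "DilutionSeries",
    "PrimerEfficiency",
    "primer_efficiency",
    "efficiency_gate",
    "opposite_profile_check",
    "read_dilution_series",
    "efficiency_report",
]

EFFICIENCY_MIN = 1.8
EFFICIENCY_MAX = 2.0


@dataclass
class DilutionSeries:
    """Cq measurements over a serial dilution.

    ``dilution_factors`` are the fold dilutions (e.g. 5, 25, ..., 3125);
    ``cq`` has one row per dilution level and one column per technical
    replicate (a 1-D array is a single replicate).
    """

    dilution_factors: np.ndarray
    cq: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dilution_factors, dtype=float)
        cq = np.asarray(self.cq, dtype=float)
        if cq.ndim == 1:
            cq = cq[:, None]
        if np.any(d <= 0):
            raise ValueError("dilution factors must be positive")
        if np.unique(d).size < 3:
            raise ValueError("need >= 3 distinct dilution levels")
        if cq.shape[0] != d.size:
            raise ValueError("one Cq row per dilution level required")
        if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
            raise ValueError("Cq values must be finite and positive")
        self.dilution_factors = d
        self.cq = cq


class PrimerEfficiency(BaseEstimator):
    """Standard-curve estimator of qPCR primer efficiency.

    Fits mean Cq against log10 of the relative template amount
    (1 / dilution factor) by least squares.

    Attributes
    ----------
    slope_ : float
        Standard-curve slope (must be negative: Cq rises with dilution).
    efficiency_ : float
        Amplification factor per cycle, ``10 ** (-1 / slope_)``.
    passes_gate_ : bool
        Whether ``efficiency_`` lies in the inclusive 1.8-2.0 band.
    """

    def fit(self, X: DilutionSeries, y=None):
        series = X
        log_amount = np.log10(1.0 / series.dilution_factors)
        mean_cq = series.cq.mean(axis=1)
        slope, _intercept = np.polyfit(log_amount, mean_cq, 1)
        if slope >= 0:
            raise ValueError(
                "invalid dilution series: Cq does not increase with dilution "
                f"(slope {slope:.4g})"
            )
        self.slope_ = float(slope)
        self.efficiency_ = float(10.0 ** (-1.0 / slope))
        self.passes_gate_ = efficiency_gate(self.efficiency_)
        return self


def primer_efficiency(series: DilutionSeries) -> float:
    """Amplification factor per cycle from a dilution series."""
    return PrimerEfficiency().fit(series).efficiency_


def efficiency_gate(E: float) -> bool:
    """Retention gate: true iff 1.8 <= E <= 2.0 (both boundaries included)."""
    if E <= 0:
        raise ValueError("efficiency must be positive")
    return EFFICIENCY_MIN <= E <= EFFICIENCY_MAX


def opposite_profile_check(
    shedding_profile,
    nonshedding_profile,
    direction: str,
    threshold: float = 0.5,
) -> str:
    """Compare ripe-stage abundance between shedding and non-shedding AZ.

    Both profiles (same condition ordering, ripe stage last) are
    peak-normalized to 1.  For a gene called ``up`` during abscission the
    prediction matches when the non-shedding ripe value is below
    ``threshold`` times the shedding ripe value; for ``down`` when it is
    above the shedding ripe value divided by ``threshold``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    shed = normalize_to_peak(shedding_profile)
    nonshed = normalize_to_peak(nonshedding_profile)
    shed_ripe = shed[-1]
    nonshed_ripe = nonshed[-1]
    if direction == "up":
        return "match" if nonshed_ripe < threshold * shed_ripe else "mismatch"
    return "match" if nonshed_ripe > shed_ripe / threshold else "mismatch"


def read_dilution_series(path) -> dict[str, DilutionSeries]:
    """Read a long-form TSV (primer_id, dilution_factor, replicate, cq)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, DilutionSeries] = {}
    for primer, grp in df.groupby("primer_id", sort=True):
        wide = grp.pivot(index="dilution_factor", columns="replicate", values="cq")
        wide = wide.sort_index()
        out[str(primer)] = DilutionSeries(
            wide.index.to_numpy(dtype=float), wide.to_numpy(dtype=float)
        )
    return out


def efficiency_report(series_by_primer: dict[str, DilutionSeries]) -> pd.DataFrame:
    """Slope, efficiency, and gate outcome per primer."""
    rows = []
    for primer in sorted(series_by_primer):
        est = PrimerEfficiency().fit(series_by_primer[primer])
        rows.append(
            {
                "primer_id": primer,
                "slope": est.slope_,
                "efficiency": est.efficiency_,
                "pass": est.passes_gate_,
            }
        )
    return pd.DataFrame(rows).set_index("primer_id")
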