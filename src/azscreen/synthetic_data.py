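"""Seeded generator of tag-count libraries with planted abscission effects.

The generator emulates the study design the screen expects: an ethylene
time course of the ripe-fruit abscission zone (AZ150, 0-12 h) with the
immature-fruit AZ (AZ30) and ripe-fruit pedicel (P150) comparator series
(0-9 h), plus a natural-abscission field series of the AZ at 30, 120 and
160 days after pollination with transcript lengths for RPKM.  Libraries
are unreplicated multiplexed tag pools, one per tissue x time point, as
in the original experiment.

Each gene carries a ground-truth label:

    az_specific_up      induced in AZ150 only, concordantly high at 160 DAP
    az_specific_down    repressed in AZ150 only, concordantly low at 160 DAP
    az_transient        single-peak (3 h or 6 h) response in AZ150 only
    shared_responsive   induced identically in AZ150, AZ30 and P150
    natural_discordant  induced in AZ150 but flat across the field series
    null                flat everywhere

Counts are Poisson(total x proportion), the sampling model of the
Audic-Claverie test itself; the unreplicated libraries of the original
design leave no overdispersion estimable, but an optional negative-
binomial mode (``dispersion``) is available for robustness experiments.
Base abundances are log-normal across genes (median 1e-5 of the library),
spanning rare to abundant tags.  A per-library background contig absorbs
the remaining read mass so that expected column sums equal the configured
totals without distorting the planted genes' proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .count_model import CountTable, SampleSheet
from .qpcr_validation import DilutionSeries

__all__ = [
    "LABELS",
    "SynthConfig",
    "SyntheticDataset",
    "generate",
    "generate_dilution_series",
    "write_truth",
    "read_truth",
]

LABELS = (
    "az_specific_up",
    "az_specific_down",
    "az_transient",
    "shared_responsive",
    "natural_discordant",
    "null",
)

BACKGROUND_ID = "background"

MIN_TOTAL = 10_000


@dataclass
class SynthConfig:
    """Configuration of the synthetic study design.

    ``n_per_label`` gives the number of genes per ground-truth label,
    ``fold`` the effect size at full induction, ``total_reads`` the
    expected mapped reads per library.  ``abundance_mu``/``abundance_sigma``
    parameterize the log-normal base abundance (natural-log scale;
    defaults give a median proportion of 1e-5 of the library).  Monotone
    effects ramp linearly from no effect at 0 h to the full fold at
    ``ramp_full_h`` (cell separation is complete by 9 h) and plateau
    after; transient effects peak at 3 h or 6 h (alternating per gene)
    and return to baseline within 3 h.  ``seed`` is mandatory.
    """

    seed: int
    n_per_label: dict[str, int] = field(
        default_factory=lambda: {label: 50 for label in LABELS}
    )
    fold: float = 8.0
    total_reads: int = 1_000_000
    abundance_mu: float = math.log(1e-5)
    abundance_sigma: float = 1.5
    az150_times_h: tuple[int, ...] = (0, 3, 6, 9, 12)
    comparator_times_h: tuple[int, ...] = (0, 3, 6, 9)
    natural_stages_dap: tuple[int, ...] = (30, 120, 160)
    ramp_full_h: float = 9.0
    transient_peaks_h: tuple[int, ...] = (3, 6)
    length_range_bp: tuple[int, int] = (500, 3000)
    dispersion: float | None = None  # NB mode when set (> 0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (reproducibility contract)")
        if self.total_reads < MIN_TOTAL:
            raise ValueError(f"total_reads must be >= {MIN_TOTAL}")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        unknown = set(self.n_per_label) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive when set")


@dataclass
class SyntheticDataset:
    """Generated tables plus the ground truth used to plant them."""

    ethylene_table: CountTable
    ethylene_sheet: SampleSheet
    natural_table: CountTable
    natural_sheet: SampleSheet
    truth: pd.DataFrame  # index contig_id; label, pi, fold
    expected_counts: pd.DataFrame  # contig x library expected counts


def _ramp(t: float, fold: float, full_h: float) -> float:
    return 1.0 + (fold - 1.0) * min(t / full_h, 1.0)


def _transient(t: float, fold: float, peak_h: float, width_h: float = 3.0) -> float:
    return 1.0 + (fold - 1.0) * max(0.0, 1.0 - abs(t - peak_h) / width_h)


def _fold_factor(label: str, cell: tuple, cfg: SynthConfig, peak_h: float) -> float:
    """Multiplicative effect of a label in one design cell.

    ``cell`` is (tissue, stage_dap, treatment, time_or_stage).  Base
    abundance pi is the low state; down-regulated genes start high
    (fold x pi) in the ripe AZ and decay to pi, and sit high at the
    pre-abscission field stages.
    """
    tissue, stage, treatment, t = cell
    f = cfg.fold
    in_az150 = treatment == "ethylene" and tissue == "AZ" and stage == 150
    if treatment == "field":
        ripe = t == max(cfg.natural_stages_dap)
        if label in ("az_specific_up", "shared_responsive"):
            return f if ripe else 1.0
        if label == "az_specific_down":
            return 1.0 if ripe else f
        return 1.0  # transient, discordant, null: flat in the field
    # ethylene arm
    if label == "az_specific_up" and in_az150:
        return _ramp(t, f, cfg.ramp_full_h)
    if label == "az_specific_down" and in_az150:
        return f + 1.0 - _ramp(t, f, cfg.ramp_full_h)
    if label == "az_transient" and in_az150:
        return _transient(t, f, peak_h)
    if label == "shared_responsive":
        return _ramp(t, f, cfg.ramp_full_h)
    if label == "natural_discordant" and in_az150:
        return _ramp(t, f, cfg.ramp_full_h)
    return 1.0


def _design_cells(cfg: SynthConfig):
    ethylene = []
    for t in sorted(cfg.az150_times_h):
        ethylene.append((f"AZ150_E{t}h", ("AZ", 150, "ethylene", t)))
    for t in sorted(cfg.comparator_times_h):
        ethylene.append((f"AZ30_E{t}h", ("AZ", 30, "ethylene", t)))
    for t in sorted(cfg.comparator_times_h):
        ethylene.append((f"P150_E{t}h", ("P", 150, "ethylene", t)))
    natural = [
        (f"AZnat_{s}DAP", ("AZ", s, "field", s)) for s in sorted(cfg.natural_stages_dap)
    ]
    return ethylene, natural


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate(cfg: SynthConfig) -> SyntheticDataset:
    """Generate ethylene and natural count tables plus ground truth."""
    rng = np.random.default_rng(cfg.seed)
    labels = [label for label in LABELS for _ in range(cfg.n_per_label.get(label, 0))]
    n_genes = len(labels)
    contig_ids = [f"contig{i:04d}" for i in range(n_genes)]
    pi = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, size=n_genes)
    peaks = np.array(
        [cfg.transient_peaks_h[i % len(cfg.transient_peaks_h)] for i in range(n_genes)],
        dtype=float,
    )
    lo, hi = cfg.length_range_bp
    lengths = rng.integers(lo, hi + 1, size=n_genes + 1)  # +1 for background

    ethylene_cells, natural_cells = _design_cells(cfg)
    all_cells = ethylene_cells + natural_cells

    # expected proportion of each gene in each library
    factors = np.empty((n_genes, len(all_cells)))
    for j, (_, cell) in enumerate(all_cells):
        for i, label in enumerate(labels):
            factors[i, j] = _fold_factor(label, cell, cfg, peaks[i])
    props = pi[:, None] * factors

    # keep the planted mass well below the library total; the background
    # contig absorbs the remainder so column sums concentrate at the total
    mass = props.sum(axis=0)
    if n_genes and mass.max() > 0.5:
        props *= 0.5 / mass.max()
        pi = pi * 0.5 / mass.max()
        mass = props.sum(axis=0)
    bg = 1.0 - mass

    mean_counts = np.vstack([props, bg[None, :]]) * float(cfg.total_reads)
    counts = _draw_counts(rng, mean_counts, cfg.dispersion)

    index = pd.Index(contig_ids + [BACKGROUND_ID], name="contig_id")
    eth_ids = [lib for lib, _ in ethylene_cells]
    nat_ids = [lib for lib, _ in natural_cells]
    n_eth = len(eth_ids)

    eth_counts = pd.DataFrame(counts[:, :n_eth], index=index, columns=eth_ids)
    nat_counts = pd.DataFrame(counts[:, n_eth:], index=index, columns=nat_ids)
    lengths_series = pd.Series(lengths, index=index, name="length_bp")

    ethylene_table = CountTable(eth_counts)
    natural_table = CountTable(nat_counts, lengths_bp=lengths_series)

    def sheet_for(cells) -> SampleSheet:
        rows = []
        for lib, (tissue, stage, treatment, t) in cells:
            rows.append(
                {
                    "library_id": lib,
                    "tissue": tissue,
                    "stage_dap": stage,
                    "treatment": treatment,
                    "time_h": t if treatment == "ethylene" else pd.NA,
                }
            )
        return SampleSheet(pd.DataFrame(rows).set_index("library_id"))

    truth = pd.DataFrame(
        {
            "label": labels + [BACKGROUND_ID],
            "pi": np.append(pi, bg.mean()),
            "fold": [cfg.fold if label != "null" else 1.0 for label in labels]
            + [1.0],
        },
        index=index,
    )
    expected = pd.DataFrame(
        mean_counts, index=index, columns=eth_ids + nat_ids
    )
    return SyntheticDataset(
        ethylene_table,
        sheet_for(ethylene_cells),
        natural_table,
        sheet_for(natural_cells),
        truth,
        expected,
    )


def generate_dilution_series(
    E_true: float,
    cq0: float = 20.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dilution_factors=(5, 25, 125, 625, 3125),
    n_replicates: int = 3,
) -> DilutionSeries:
    """Simulate a qPCR standard curve with true per-cycle factor ``E_true``.

    ``Cq(d) = cq0 + log(d)/log(E_true) + Normal(0, noise_sd)`` per
    technical replicate.
    """
    if not 1.0 < E_true <= 2.5:
        raise ValueError("E_true must lie in (1, 2.5]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if seed is None:
        raise ValueError("a seed is mandatory (reproducibility contract)")
    rng = np.random.default_rng(seed)
    d = np.asarray(dilution_factors, dtype=float)
    cq = cq0 + np.log(d)[:, None] / math.log(E_true)
    cq = cq + rng.normal(0.0, noise_sd, size=(d.size, n_replicates))
    return DilutionSeries(d, cq)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", lineterminator="\n", float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="contig_id")
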