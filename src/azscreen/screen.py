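"""The four-stage multi-scale screen for abscission-zone-specific,
abscission-timed genes.

Stage 1 — ethylene time-course DEG calling: every treated time point of
the ripe-fruit AZ (AZ150) is tested against the untreated 0 h library
with the exact Audic-Claverie test, Bonferroni-adjusted within each
pairwise comparison; a contig is a DEG when adjusted p <= alpha at a
minimum number of time points.

Stage 2 — tissue specificity: a DEG is kept only if, at some shared time
point (0-9 h), the AZ150 library differs significantly from BOTH the
immature-fruit AZ (AZ30) and the ripe-fruit pedicel (P150) — and, by
default, in the same direction versus both.  A gene higher than one
comparator but lower than the other is not tissue-specific.

Stage 3 — the natural-abscission field time course of the AZ (30, 120,
160 days after pollination) provides RPKM profiles.

Stage 4 — concordance: a candidate whose ethylene direction (sustained
up, sustained down, or transient, from the shape of its AZ150 profile)
agrees with its natural-profile direction enters the final up or down
set.  Transient genes qualify only when their natural direction is
non-flat and matches the sign of their net 0 h -> last time point change.

`AbscissionScreen` is the estimator interface; `run_screen` is a
functional wrapper returning the same `ScreenResult`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from . import ac_test
from .count_model import CountTable, CountTableError, SampleSheet, cpm_matrix, rpkm_matrix
from .profile_tools import classify_shape, natural_direction

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "AbscissionScreen",
    "stage1_ethylene_degs",
    "stage2_tissue_filter",
    "ethylene_directions",
    "stage4_concordance",
    "run_screen",
    "summarize_classes",
    "write_report",
]

AUDIT_COLUMNS = [
    "stage",
    "comparison",
    "contig_id",
    "x",
    "y",
    "N1",
    "N2",
    "p_raw",
    "p_adj",
    "direction",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and design constants of the screen.

    alpha: significance level on Bonferroni-adjusted p-values.
    min_timepoints: time points at which a contig must be significant to
        be a stage-1 DEG.
    stage1_times_h: ethylene time course of the AZ150 series (0 h is the
        control).
    shared_times_h: time points at which AZ150 and both comparator series
        exist (the comparators stop at 9 h; the 12 h AZ150 library serves
        stage 1 only).
    natural_fold_threshold: fold change defining up/down across the
        natural time course.
    require_same_direction: stage-2 candidates must differ from both
        comparators in the same direction.
    """

    alpha: float = 0.01
    min_timepoints: int = 1
    stage1_times_h: tuple[int, ...] = (0, 3, 6, 9, 12)
    shared_times_h: tuple[int, ...] = (0, 3, 6, 9)
    natural_fold_threshold: float = 2.0
    require_same_direction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_timepoints < 1:
            raise ValueError("min_timepoints must be >= 1")
        if self.natural_fold_threshold <= 1:
            raise ValueError("natural_fold_threshold must be > 1")
        if 0 not in self.stage1_times_h:
            raise ValueError("stage-1 times must include the 0 h control")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stage1_times_h", "shared_times_h"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScreenResult:
    """Nested contig sets surviving the screen, with a full audit trail.

    Invariants: final_up | final_down <= stage2_candidates <=
    stage1_degs, and final_up is disjoint from final_down.
    """

    stage1_degs: pd.Index
    stage1_sig_counts: pd.Series  # contig -> number of significant time points
    stage2_candidates: pd.Index
    final_up: pd.Index
    final_down: pd.Index
    ethylene_direction: pd.Series  # stage-2 candidates -> up/down/transient
    natural_direction: pd.Series  # stage-2 candidates -> up/down/flat
    audit: pd.DataFrame
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        s1, s2 = set(self.stage1_degs), set(self.stage2_candidates)
        final = set(self.final_up) | set(self.final_down)
        assert s2 <= s1, "stage-2 candidates must nest inside stage-1 DEGs"
        assert final <= s2, "final sets must nest inside stage-2 candidates"
        assert not (set(self.final_up) & set(self.final_down))


def _audit_frame(stage: str, comparison: str, result: pd.DataFrame) -> pd.DataFrame:
    df = result.reset_index()
    df.insert(0, "comparison", comparison)
    df.insert(0, "stage", stage)
    return df[AUDIT_COLUMNS]


def stage1_ethylene_degs(
    table: CountTable,
    sheet: SampleSheet,
    cfg: ScreenConfig,
) -> tuple[pd.Index, pd.Series, pd.DataFrame]:
    """Call ethylene-responsive DEGs in the AZ150 series.

    Returns (DEG index, per-contig count of significant time points,
    audit rows).  The Bonferroni family is the number of contigs within
    each pairwise comparison.
    """
    lib0 = sheet.library("AZ", 150, "ethylene", 0)  # raises if absent
    treated = [t for t in sorted(cfg.stage1_times_h) if t != 0]
    n_sig = pd.Series(0, index=table.contig_ids, dtype=int)
    audits = []
    for t in treated:
        lib_t = sheet.library("AZ", 150, "ethylene", t)
        res = ac_test.compare_libraries(table, lib0, lib_t, m=len(table.contig_ids))
        n_sig += (res["p_adj"] <= cfg.alpha).astype(int)
        audits.append(_audit_frame("stage1", f"AZ150_{t}h_vs_0h", res))
    degs = n_sig.index[n_sig >= cfg.min_timepoints]
    audit = (
        pd.concat(audits, ignore_index=True)
        if audits
        else pd.DataFrame(columns=AUDIT_COLUMNS)
    )
    return degs, n_sig, audit


def stage2_tissue_filter(
    degs: Iterable[str],
    table: CountTable,
    sheet: SampleSheet,
    cfg: ScreenConfig,
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep DEGs specific to the ripe-fruit AZ.

    A DEG survives when at some shared time point the AZ150 library
    differs significantly (adjusted p <= alpha) from both AZ30 and P150,
    in a consistent direction when ``require_same_direction`` is set.
    """
    degs = pd.Index(degs)
    if len(degs) == 0:
        return degs, pd.DataFrame(columns=AUDIT_COLUMNS)
    sub = table.subset(degs)
    retained = pd.Series(False, index=degs)
    audits = []
    n_times_available = 0
    for t in sorted(cfg.shared_times_h):
        try:
            lib_az150 = sheet.library("AZ", 150, "ethylene", t)
            lib_az30 = sheet.library("AZ", 30, "ethylene", t)
            lib_p150 = sheet.library("P", 150, "ethylene", t)
        except CountTableError:
            logger.warning("stage 2: incomplete design at %d h; skipped", t)
            continue
        n_times_available += 1
        vs_az30 = ac_test.compare_libraries(sub, lib_az30, lib_az150, m=len(degs))
        vs_p150 = ac_test.compare_libraries(sub, lib_p150, lib_az150, m=len(degs))
        audits.append(_audit_frame("stage2", f"AZ150_vs_AZ30_{t}h", vs_az30))
        audits.append(_audit_frame("stage2", f"AZ150_vs_P150_{t}h", vs_p150))
        hit = (vs_az30["p_adj"] <= cfg.alpha) & (vs_p150["p_adj"] <= cfg.alpha)
        if cfg.require_same_direction:
            hit &= (vs_az30["direction"] == vs_p150["direction"]) & (
                vs_az30["direction"] != "none"
            )
        retained |= hit
    if n_times_available == 0:
        raise CountTableError(
            "stage 2: comparator tissues missing at every shared time point"
        )
    audit = pd.concat(audits, ignore_index=True)
    return degs[retained], audit


def ethylene_directions(
    table: CountTable,
    sheet: SampleSheet,
    contigs: Iterable[str],
    cfg: ScreenConfig,
) -> tuple[pd.Series, pd.Series]:
    """Direction of each contig's ethylene response in the AZ150 series.

    The AZ150 counts-per-million profile over the stage-1 time course is
    shape-classified: sustained induction -> up, repression -> down,
    single-peak or unclassifiable -> transient.  Also returns the sign of
    the net 0 h -> last time point change (+1/-1/0), used to resolve
    transient genes at stage 4.
    """
    contigs = pd.Index(contigs)
    times = sorted(cfg.stage1_times_h)
    libs = [sheet.library("AZ", 150, "ethylene", t) for t in times]
    cpm = cpm_matrix(table).loc[contigs, libs]
    values = cpm.to_numpy()
    directions = []
    for row in values:
        if len(row) == 5:
            shape = classify_shape(row)
        else:
            shape = "other"
        directions.append(
            {"A": "up", "D": "down"}.get(shape, "transient")
        )
    net = np.sign(values[:, -1] - values[:, 0]).astype(int) if len(contigs) else np.array([], dtype=int)
    return (
        pd.Series(directions, index=contigs, name="ethylene_direction"),
        pd.Series(net, index=contigs, name="net_sign"),
    )


def stage4_concordance(
    candidates: Iterable[str],
    eth_direction: pd.Series,
    net_sign: pd.Series,
    natural_table: CountTable,
    natural_sheet: SampleSheet,
    cfg: ScreenConfig,
) -> tuple[pd.Index, pd.Index, pd.Series, list[str]]:
    """Intersect ethylene candidates with the natural-abscission profile.

    Returns (final_up, final_down, natural direction per candidate,
    unresolved candidates absent from the natural table).
    """
    candidates = pd.Index(candidates)
    stages = sorted(
        natural_sheet.select(treatment="field")["stage_dap"].unique().tolist()
    )
    if len(stages) < 3:
        raise CountTableError("natural series needs >= 3 field stages")
    libs = [natural_sheet.library("AZ", s, "field") for s in stages]
    rpkm = rpkm_matrix(natural_table)
    unresolved = [c for c in candidates if c not in rpkm.index]
    for c in unresolved:
        logger.warning("candidate %s absent from the natural table; excluded", c)
    resolved = candidates[~candidates.isin(unresolved)]
    nat_dir = pd.Series(
        [
            natural_direction(
                *(rpkm.at[c, lib] for lib in libs[-3:]),
                fold=cfg.natural_fold_threshold,
            )
            for c in resolved
        ],
        index=resolved,
        dtype=object,
        name="natural_direction",
    )
    up_mask, down_mask = [], []
    for c in resolved:
        eth = eth_direction.at[c]
        nat = nat_dir.at[c]
        if eth == "up":
            up_mask.append(nat == "up")
            down_mask.append(False)
        elif eth == "down":
            up_mask.append(False)
            down_mask.append(nat == "down")
        else:  # transient: natural must be non-flat and match the net change
            up_mask.append(nat == "up" and net_sign.at[c] > 0)
            down_mask.append(nat == "down" and net_sign.at[c] < 0)
    final_up = resolved[np.array(up_mask, dtype=bool)] if len(resolved) else resolved
    final_down = resolved[np.array(down_mask, dtype=bool)] if len(resolved) else resolved
    return final_up, final_down, nat_dir, unresolved


class AbscissionScreen(BaseEstimator):
    """Estimator interface to the four-stage screen.

    Parameters mirror :class:`ScreenConfig`.  After :meth:`fit` the
    nested result sets are available as ``stage1_degs_``,
    ``stage2_candidates_``, ``final_up_``, ``final_down_``, with the full
    per-test audit trail in ``audit_`` and the complete
    :class:`ScreenResult` in ``result_``.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_timepoints: int = 1,
        stage1_times_h: tuple[int, ...] = (0, 3, 6, 9, 12),
        shared_times_h: tuple[int, ...] = (0, 3, 6, 9),
        natural_fold_threshold: float = 2.0,
        require_same_direction: bool = True,
    ):
        self.alpha = alpha
        self.min_timepoints = min_timepoints
        self.stage1_times_h = stage1_times_h
        self.shared_times_h = shared_times_h
        self.natural_fold_threshold = natural_fold_threshold
        self.require_same_direction = require_same_direction

    def _config(self) -> ScreenConfig:
        return ScreenConfig(
            alpha=self.alpha,
            min_timepoints=self.min_timepoints,
            stage1_times_h=tuple(self.stage1_times_h),
            shared_times_h=tuple(self.shared_times_h),
            natural_fold_threshold=self.natural_fold_threshold,
            require_same_direction=self.require_same_direction,
        )

    def fit(
        self,
        ethylene_table: CountTable,
        ethylene_sheet: SampleSheet,
        natural_table: CountTable,
        natural_sheet: SampleSheet,
    ):
        cfg = self._config()
        ethylene_sheet.validate_against(ethylene_table)
        natural_sheet.validate_against(natural_table)

        degs, n_sig, audit1 = stage1_ethylene_degs(ethylene_table, ethylene_sheet, cfg)
        logger.info("stage 1: %d DEGs of %d contigs", len(degs), len(n_sig))
        candidates, audit2 = stage2_tissue_filter(degs, ethylene_table, ethylene_sheet, cfg)
        logger.info("stage 2: %d candidates retained", len(candidates))
        eth_dir, net = ethylene_directions(ethylene_table, ethylene_sheet, candidates, cfg)
        final_up, final_down, nat_dir, unresolved = stage4_concordance(
            candidates, eth_dir, net, natural_table, natural_sheet, cfg
        )
        logger.info(
            "stage 4: %d up, %d down (%d unresolved)",
            len(final_up),
            len(final_down),
            len(unresolved),
        )
        frames = [a for a in (audit1, audit2) if not a.empty]
        audit = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=AUDIT_COLUMNS)
        )
        self.result_ = ScreenResult(
            stage1_degs=degs,
            stage1_sig_counts=n_sig,
            stage2_candidates=candidates,
            final_up=final_up,
            final_down=final_down,
            ethylene_direction=eth_dir,
            natural_direction=nat_dir,
            audit=audit,
            unresolved=unresolved,
        )
        self.stage1_degs_ = degs
        self.stage2_candidates_ = candidates
        self.final_up_ = final_up
        self.final_down_ = final_down
        self.audit_ = audit
        return self


def run_screen(
    ethylene_table: CountTable,
    ethylene_sheet: SampleSheet,
    natural_table: CountTable,
    natural_sheet: SampleSheet,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Run stages 1 -> 2 -> (profile directions) -> 4 and return the result."""
    cfg = cfg or ScreenConfig()
    est = AbscissionScreen(
        alpha=cfg.alpha,
        min_timepoints=cfg.min_timepoints,
        stage1_times_h=cfg.stage1_times_h,
        shared_times_h=cfg.shared_times_h,
        natural_fold_threshold=cfg.natural_fold_threshold,
        require_same_direction=cfg.require_same_direction,
    )
    return est.fit(ethylene_table, ethylene_sheet, natural_table, natural_sheet).result_


def summarize_classes(
    final_contigs: Iterable[str],
    annotation: Mapping[str, str] | None,
) -> pd.Series:
    """Tally final contigs per functional class (unannotated -> unknown)."""
    annotation = annotation or {}
    classes = [annotation.get(c, "unknown") for c in final_contigs]
    tally = pd.Series(classes, dtype=object).value_counts()
    return tally.sort_index().astype(int)


def write_report(result: ScreenResult, outdir: str | Path,
                 annotation: Mapping[str, str] | None = None) -> None:
    """Write the screen outputs as deterministic TSVs.

    stage1_degs.tsv, stage2_candidates.tsv, final_up.tsv, final_down.tsv,
    audit.tsv and (when an annotation map is given) class_summary.tsv.
    Identical inputs and config produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def write_set(name: str, contigs: pd.Index, extra: dict | None = None) -> None:
        df = pd.DataFrame(index=pd.Index(sorted(contigs), name="contig_id"))
        if extra:
            for col, series in extra.items():
                df[col] = series.reindex(df.index)
        df.to_csv(outdir / name, sep="\t", lineterminator="\n")

    write_set(
        "stage1_degs.tsv",
        result.stage1_degs,
        {"n_significant_times": result.stage1_sig_counts},
    )
    write_set(
        "stage2_candidates.tsv",
        result.stage2_candidates,
        {"ethylene_direction": result.ethylene_direction},
    )
    write_set(
        "final_up.tsv",
        result.final_up,
        {"natural_direction": result.natural_direction},
    )
    write_set(
        "final_down.tsv",
        result.final_down,
        {"natural_direction": result.natural_direction},
    )
    audit = result.audit.sort_values(["stage", "comparison", "contig_id"]).reset_index(
        drop=True
    )
    audit.to_csv(outdir / "audit.tsv", sep="\t", index=False,
                 lineterminator="\n", float_format="%.6g")
    if annotation is not None:
        final = list(result.final_up) + list(result.final_down)
        tally = summarize_classes(final, annotation)
        tally.rename_axis("class").rename("count").to_csv(
            outdir / "class_summary.tsv", sep="\t", lineterminator="\n"
        )
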