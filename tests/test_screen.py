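"""The four-stage screen: stage logic, funnel invariants, reporting."""

import numpy as np
import pandas as pd
import pytest

from azscreen.count_model import CountTable, CountTableError, SampleSheet
from azscreen.screen import (
    AbscissionScreen,
    ScreenConfig,
    ScreenResult,
    ethylene_directions,
    run_screen,
    stage1_ethylene_degs,
    stage2_tissue_filter,
    stage4_concordance,
    summarize_classes,
    write_report,
)
from azscreen.synthetic_data import LABELS, SynthConfig, generate

from conftest import make_ethylene_design, make_natural_design
from _oracles import ac_pvalue_by_summation

TOTALS = 10**5


def ethylene_fixture(gene_counts):
    """gene_counts: dict contig -> dict library -> count (missing -> baseline 5)."""
    libs = [f"AZ150_E{t}h" for t in (0, 3, 6, 9, 12)]
    libs += [f"AZ30_E{t}h" for t in (0, 3, 6, 9)]
    libs += [f"P150_E{t}h" for t in (0, 3, 6, 9)]
    counts = {
        lib: [gene_counts[g].get(lib, 5) for g in gene_counts] for lib in libs
    }
    table, sheet = make_ethylene_design(counts)
    table = CountTable(
        table.counts.set_axis(pd.Index(list(gene_counts), name="contig_id")),
        library_totals=pd.Series(TOTALS, index=table.library_ids),
    )
    return table, sheet


class TestStage1:
    def test_strong_induction_retained_weak_not(self):
        """Gene going 5 -> 200 reads is a DEG after Bonferroni (family 3);
        50 -> 55 is not.  Expected calls verified with the summation
        oracle."""
        table, sheet = ethylene_fixture(
            {
                "strong": {"AZ150_E0h": 5, "AZ150_E12h": 200},
                "weak": {f"AZ150_E{t}h": 50 for t in (0, 3, 6, 9)} | {"AZ150_E12h": 55},
                "flat": {},
            }
        )
        degs, n_sig, audit = stage1_ethylene_degs(table, sheet, ScreenConfig())
        assert ac_pvalue_by_summation(5, 200, TOTALS, TOTALS) * 3 < 0.01
        assert ac_pvalue_by_summation(50, 55, TOTALS, TOTALS) * 3 > 0.5
        assert list(degs) == ["strong"]
        assert n_sig["strong"] >= 1 and n_sig["weak"] == 0
        assert set(audit["comparison"]) == {
            "AZ150_3h_vs_0h", "AZ150_6h_vs_0h", "AZ150_9h_vs_0h", "AZ150_12h_vs_0h",
        }

    def test_empty_table_gives_empty_degs(self):
        table, sheet = ethylene_fixture({"g": {}})
        empty = CountTable(table.counts.iloc[:0], table.library_totals)
        degs, _, _ = stage1_ethylene_degs(empty, sheet, ScreenConfig())
        assert len(degs) == 0

    def test_missing_control_is_error(self):
        table, sheet = ethylene_fixture({"g": {}})
        no_ctrl = SampleSheet(sheet.data.drop("AZ150_E0h"))
        sub = CountTable(
            table.counts.drop(columns="AZ150_E0h"),
            table.library_totals.drop("AZ150_E0h"),
        )
        with pytest.raises(CountTableError, match="no library"):
            stage1_ethylene_degs(sub, no_ctrl, ScreenConfig())


class TestStage2:
    def test_specific_gene_retained_shared_excluded(self):
        table, sheet = ethylene_fixture(
            {
                # higher in AZ150 than both comparators at 6 h
                "specific": {"AZ150_E6h": 300, "AZ30_E6h": 4, "P150_E6h": 5},
                # differs from P150 only; AZ30 matches AZ150
                "half": {"AZ150_E6h": 300, "AZ30_E6h": 290, "P150_E6h": 5},
                "flat": {},
            }
        )
        retained, audit = stage2_tissue_filter(
            ["specific", "half", "flat"], table, sheet, ScreenConfig()
        )
        assert list(retained) == ["specific"]
        assert set(audit["stage"]) == {"stage2"}

    def test_empty_input_empty_output(self):
        table, sheet = ethylene_fixture({"g": {}})
        retained, audit = stage2_tissue_filter([], table, sheet, ScreenConfig())
        assert len(retained) == 0 and audit.empty

    def test_opposite_directions_excluded_when_required(self):
        """Higher than one comparator but lower than the other is not
        tissue-specific under the default config."""
        gene = {"AZ150_E6h": 300, "AZ30_E6h": 2000, "P150_E6h": 5}
        table, sheet = ethylene_fixture({"mixed": gene, "pad": {}})
        strict, _ = stage2_tissue_filter(["mixed"], table, sheet, ScreenConfig())
        assert len(strict) == 0
        lax, _ = stage2_tissue_filter(
            ["mixed"], table, sheet, ScreenConfig(require_same_direction=False)
        )
        assert list(lax) == ["mixed"]


class TestStage4:
    def make_inputs(self, natural_counts):
        ids = list(natural_counts)
        nat_table, nat_sheet = make_natural_design(
            {
                lib: [natural_counts[g][i] for g in ids]
                for i, lib in enumerate(["AZnat_30DAP", "AZnat_120DAP", "AZnat_160DAP"])
            },
            lengths_bp=1000,
            totals=pd.Series(
                {"AZnat_30DAP": 10**6, "AZnat_120DAP": 10**6, "AZnat_160DAP": 10**6}
            ),
            contig_ids=ids,
        )
        return nat_table, nat_sheet

    def test_concordance_rules(self):
        """RPKM triplets (1,2,40) -> up; (10,11,9) -> flat; (50,40,2) -> down
        (length 1000 bp and totals 1e6 make RPKM equal the raw count)."""
        nat_table, nat_sheet = self.make_inputs(
            {"u": (1, 2, 40), "f": (10, 11, 9), "d": (50, 40, 2)}
        )
        eth_dir = pd.Series({"u": "up", "f": "up", "d": "down"})
        net = pd.Series({"u": 1, "f": 1, "d": -1})
        up, down, nat_dir, unresolved = stage4_concordance(
            ["u", "f", "d"], eth_dir, net, nat_table, nat_sheet, ScreenConfig()
        )
        assert list(up) == ["u"] and list(down) == ["d"]
        assert nat_dir.tolist() == ["up", "flat", "down"]
        assert unresolved == []

    def test_transient_needs_matching_net_sign(self):
        nat_table, nat_sheet = self.make_inputs(
            {"t_up": (1, 2, 40), "t_wrong": (1, 2, 40)}
        )
        eth_dir = pd.Series({"t_up": "transient", "t_wrong": "transient"})
        net = pd.Series({"t_up": 1, "t_wrong": -1})
        up, down, _, _ = stage4_concordance(
            ["t_up", "t_wrong"], eth_dir, net, nat_table, nat_sheet, ScreenConfig()
        )
        assert list(up) == ["t_up"] and len(down) == 0

    def test_candidate_missing_from_natural_table_is_unresolved(self):
        nat_table, nat_sheet = self.make_inputs({"present": (1, 2, 40)})
        eth_dir = pd.Series({"present": "up", "ghost": "up"})
        net = pd.Series({"present": 1, "ghost": 1})
        up, down, _, unresolved = stage4_concordance(
            ["present", "ghost"], eth_dir, net, nat_table, nat_sheet, ScreenConfig()
        )
        assert unresolved == ["ghost"]
        assert list(up) == ["present"]


class TestEthyleneDirections:
    def test_shape_to_direction_mapping(self):
        table, sheet = ethylene_fixture(
            {
                "up": {f"AZ150_E{t}h": v for t, v in zip((0, 3, 6, 9, 12), (5, 10, 20, 40, 80))},
                "down": {f"AZ150_E{t}h": v for t, v in zip((0, 3, 6, 9, 12), (80, 40, 20, 10, 5))},
                "peak3": {f"AZ150_E{t}h": v for t, v in zip((0, 3, 6, 9, 12), (5, 90, 10, 5, 5))},
            }
        )
        directions, net = ethylene_directions(
            table, sheet, ["up", "down", "peak3"], ScreenConfig()
        )
        assert directions.tolist() == ["up", "down", "transient"]
        assert net.tolist() == [1, -1, 0]


class TestRunScreen:
    def test_planted_up_genes_all_recovered_at_depth(self):
        """20 AZ-specific up genes at 8-fold with deep libraries all reach
        the final up set."""
        cfg = SynthConfig(
            seed=21,
            n_per_label={"az_specific_up": 20, "null": 100},
            total_reads=10**7,
            abundance_sigma=0.8,
        )
        d = generate(cfg)
        res = run_screen(
            d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet
        )
        planted = set(d.truth.index[d.truth.label == "az_specific_up"])
        assert planted <= set(res.final_up)

    def test_shared_only_dataset_yields_empty_finals(self):
        cfg = SynthConfig(
            seed=22,
            n_per_label={"shared_responsive": 30},
            total_reads=10**6,
        )
        d = generate(cfg)
        res = run_screen(
            d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet
        )
        planted = set(d.truth.index[d.truth.label == "shared_responsive"])
        assert not (planted & (set(res.final_up) | set(res.final_down)))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_funnel_nesting(self, seed):
        d = generate(SynthConfig(seed=seed, n_per_label={l: 10 for l in LABELS}))
        res = run_screen(
            d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet
        )
        final = set(res.final_up) | set(res.final_down)
        assert final <= set(res.stage2_candidates) <= set(res.stage1_degs)
        assert not (set(res.final_up) & set(res.final_down))

    def test_monotone_in_alpha(self):
        d = generate(SynthConfig(seed=4, n_per_label={l: 10 for l in LABELS}))
        sets = []
        for alpha in (0.0001, 0.01, 0.2):
            res = run_screen(
                d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet,
                ScreenConfig(alpha=alpha),
            )
            sets.append((set(res.stage1_degs), set(res.stage2_candidates)))
        assert sets[0][0] <= sets[1][0] <= sets[2][0]
        assert sets[0][1] <= sets[1][1] <= sets[2][1]

    def test_estimator_interface(self):
        d = generate(SynthConfig(seed=5, n_per_label={l: 5 for l in LABELS}))
        est = AbscissionScreen(alpha=0.05)
        assert est.get_params()["alpha"] == 0.05
        est.fit(d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet)
        assert set(est.final_up_) <= set(est.stage1_degs_)
        assert est.result_.audit.columns.tolist()[:3] == ["stage", "comparison", "contig_id"]


class TestReporting:
    def test_reports_are_deterministic(self, tmp_path, synth_default):
        d = synth_default
        res = run_screen(
            d.ethylene_table, d.ethylene_sheet, d.natural_table, d.natural_sheet
        )
        for sub in ("r1", "r2"):
            write_report(res, tmp_path / sub, annotation={})
        for name in ("stage1_degs.tsv", "stage2_candidates.tsv", "final_up.tsv",
                     "final_down.tsv", "audit.tsv", "class_summary.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() == (
                tmp_path / "r2" / name
            ).read_bytes()

    def test_summarize_classes(self):
        tally = summarize_classes(
            ["a", "b", "c"], {"a": "metabolism", "b": "metabolism", "c": "stress"}
        )
        assert tally.to_dict() == {"metabolism": 2, "stress": 1}
        assert summarize_classes([], {}).empty
        tally = summarize_classes(["a", "b", "c", "d", "e"],
                                  {"a": "cell wall", "b": "stress", "c": "stress"})
        assert tally.to_dict() == {"cell wall": 1, "stress": 2, "unknown": 2}

    def test_result_invariant_enforced(self):
        with pytest.raises(AssertionError):
            ScreenResult(
                stage1_degs=pd.Index(["a"]),
                stage1_sig_counts=pd.Series({"a": 1}),
                stage2_candidates=pd.Index(["a", "b"]),  # not nested
                final_up=pd.Index([]),
                final_down=pd.Index([]),
                ethylene_direction=pd.Series(dtype=object),
                natural_direction=pd.Series(dtype=object),
                audit=pd.DataFrame(),
            )


def test_config_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        ScreenConfig(alpha=0.0)
    with pytest.raises(ValueError):
        ScreenConfig(min_timepoints=0)
    with pytest.raises(ValueError):
        ScreenConfig(natural_fold_threshold=1.0)
    path = tmp_path / "cfg.yaml"
    path.write_text("alpha: 0.05\nshared_times_h: [0, 3, 6]\n")
    cfg = ScreenConfig.from_yaml(path)
    assert cfg.alpha == 0.05 and cfg.shared_times_h == (0, 3, 6)
    path.write_text("bogus: 1\n")
    with pytest.raises(ValueError, match="unknown config"):
        ScreenConfig.from_yaml(path)
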