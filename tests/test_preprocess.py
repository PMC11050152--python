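import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahmix.errors import ConfigurationError, MissingControlError
from pahmix.preprocess import (
    dunnett_vs_control,
    filter_treatments,
    fold_change_from_ct,
    read_response_csv,
    remove_outliers,
    select_genes_for_ia,
    significance_table,
    write_response_csv,
)
from pahmix.simulate import MODELED_GENES, reference_significance_pattern


def _ct_table(ct_target, rel_concs, gene="G", treatment="T", ct_reference=20.0):
    return pd.DataFrame(
        {
            "gene": gene,
            "treatment": treatment,
            "rel_conc": rel_concs,
            "replicate": range(1, len(ct_target) + 1),
            "ct_target": ct_target,
            "ct_reference": ct_reference,
        }
    )


def _response(cells, gene="G", treatment="T"):
    """cells: {rel_conc: [values]} -> long table."""
    rows = [
        {"gene": gene, "treatment": treatment, "rel_conc": rc,
         "replicate": i + 1, "log2fc": v}
        for rc, values in cells.items()
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


class TestFoldChange:
    def test_identical_cts_give_zero(self):
        ct = _ct_table([25.0] * 6, [0, 0, 0.01, 0.01, 0.1, 0.1])
        out = fold_change_from_ct(ct)
        assert (out["log2fc"] == 0).all()

    def test_one_cycle_below_vehicle_is_plus_one(self):
        # treated ΔCt one cycle below the vehicle mean => doubling
        ct = _ct_table([25.0, 25.0, 24.0], [0, 0, 0.1])
        out = fold_change_from_ct(ct)
        assert out.loc[out["rel_conc"] == 0.1, "log2fc"].iloc[0] == pytest.approx(1.0)

    def test_intended_plus_two_round_trip(self):
        # algebraic inversion: log2fc = +2 <=> ΔΔCt = -2
        ct = _ct_table([25.0, 25.0, 23.0], [0, 0, 0.1])
        out = fold_change_from_ct(ct)
        assert out.loc[out["rel_conc"] == 0.1, "log2fc"].iloc[0] == pytest.approx(2.0)

    @settings(deadline=None, max_examples=30)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_reference_shift_invariance(self, shift):
        ct = _ct_table([25.0, 24.6, 23.0, 22.5], [0, 0, 0.1, 0.1])
        shifted = ct.copy()
        shifted["ct_target"] += shift
        shifted["ct_reference"] += shift
        a = fold_change_from_ct(ct)["log2fc"]
        b = fold_change_from_ct(shifted)["log2fc"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_missing_vehicle_raises_with_names(self):
        ct = _ct_table([25.0, 24.0], [0.1, 0.1], gene="CYP1A1", treatment="retene")
        with pytest.raises(MissingControlError, match="CYP1A1.*retene"):
            fold_change_from_ct(ct)


class TestOutliers:
    def test_method_none_is_identity(self):
        df = _response({0.1: [0.1, 0.0, -0.1, 25.0]})
        out, log = remove_outliers(df, method="none")
        pd.testing.assert_frame_equal(out, df)
        assert log == []

    def test_iqr_flags_hand_computed_fence(self):
        # Q1=-0.025, Q3=6.325, upper fence 15.85 -> only 25.0 is outside
        df = _response({0.1: [0.1, 0.0, -0.1, 25.0]})
        out, log = remove_outliers(df, method="iqr", k=1.5)
        assert len(out) == 3
        assert 25.0 not in out["log2fc"].values
        assert log[0]["log2fc"] == 25.0

    @pytest.mark.parametrize("method", ["iqr", "grubbs"])
    def test_all_equal_values_nothing_removed(self, method):
        df = _response({0.1: [0.5] * 5})
        out, _ = remove_outliers(df, method=method)
        assert len(out) == 5

    def test_grubbs_removes_gross_outlier(self):
        df = _response({0.1: [0.1, -0.2, 0.0, 0.15, 12.0]})
        out, log = remove_outliers(df, method="grubbs", alpha=0.05)
        assert 12.0 not in out["log2fc"].values

    def test_small_cells_skipped_and_logged(self):
        df = _response({0.1: [0.0, 30.0]})
        out, log = remove_outliers(df, method="iqr")
        assert len(out) == 2
        assert log[0]["action"] == "skipped"


class TestDunnett:
    def test_exact_ties_give_p_one(self):
        df = _response({0.0: [1.0] * 4, 0.01: [1.0] * 4, 0.1: [1.0] * 4})
        with pytest.warns(UserWarning, match="tied"):
            recs = dunnett_vs_control(df, "G", "T")
        assert all(r.p_adj == 1.0 and not r.significant for r in recs)

    def test_ten_sd_shift_is_overwhelming(self):
        rng = np.random.default_rng(5)
        df = _response(
            {
                0.0: rng.normal(0, 1, 6),
                0.01: rng.normal(0, 1, 6),
                0.1: rng.normal(10, 1, 6),
            }
        )
        recs = {r.rel_conc: r for r in dunnett_vs_control(df, "G", "T")}
        assert recs[0.1].p_adj < 1e-6 and recs[0.1].significant
        assert not recs[0.01].significant

    def test_zero_variance_separated_means_significant(self):
        df = _response({0.0: [0.0] * 4, 0.1: [2.0] * 4})
        recs = dunnett_vs_control(df, "G", "T")
        assert recs[0].p_adj == 0.0 and recs[0].significant

    def test_requires_two_observations_per_group(self):
        df = _response({0.0: [0.0, 0.1], 0.1: [1.0]})
        with pytest.raises(ConfigurationError):
            dunnett_vs_control(df, "G", "T")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_agrees_with_multcomp_reference(self, tmp_path):
        """Cross-check the Dunnett p-values against R's multcomp::glht."""
        rng = np.random.default_rng(42)
        cells = {
            0.0: rng.normal(0.0, 0.5, 5),
            0.01: rng.normal(0.3, 0.5, 5),
            0.05: rng.normal(0.8, 0.5, 5),
            0.1: rng.normal(1.5, 0.5, 5),
        }
        df = _response(cells)
        ours = {r.rel_conc: r.p_adj for r in dunnett_vs_control(df, "G", "T")}
        csv = tmp_path / "cells.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "dunnett.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(multcomp))
            d <- read.csv("{csv}")
            d$grp <- relevel(factor(d$rel_conc), ref = "0")
            fit <- aov(log2fc ~ grp, data = d)
            ht <- glht(fit, linfct = mcp(grp = "Dunnett"))
            p <- summary(ht)$test$pvalues
            cat(paste(p, collapse = "\\n"))
        """))
        res = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        ref = [float(v) for v in res.stdout.strip().splitlines()]
        for ours_p, ref_p in zip([ours[0.01], ours[0.05], ours[0.1]], ref):
            assert ours_p == pytest.approx(ref_p, abs=0.01)


class TestFilters:
    def test_cell_below_min_obs_removed_and_logged(self):
        df = pd.concat(
            [
                _response({0.0: [0, 0, 0], 0.1: [1.0]}, treatment="benzo[e]pyrene",
                          gene="CYP1A1"),
                _response({0.0: [0, 0, 0], 0.1: [1.0, 1.1]}, treatment="retene",
                          gene="CYP1A1"),
            ],
            ignore_index=True,
        )
        out, log = filter_treatments(df, min_obs=2)
        kept = out[(out["treatment"] == "benzo[e]pyrene") & (out["rel_conc"] > 0)]
        assert kept.empty
        assert len(log) == 1 and log[0]["treatment"] == "benzo[e]pyrene"
        # exactly min_obs observations are retained (inclusive boundary)
        assert len(out[(out["treatment"] == "retene") & (out["rel_conc"] > 0)]) == 2

    def test_min_obs_one_keeps_everything(self):
        df = _response({0.0: [0, 0], 0.1: [1.0]})
        out, log = filter_treatments(df, min_obs=1)
        assert len(out) == len(df) and not log

    def test_filter_is_idempotent(self):
        df = _response({0.0: [0, 0, 0], 0.05: [1.0], 0.1: [1.0, 1.1]})
        once, _ = filter_treatments(df, min_obs=2)
        twice, log2 = filter_treatments(once, min_obs=2)
        pd.testing.assert_frame_equal(once, twice)
        assert not log2


class TestGeneSelection:
    def test_reference_pattern_selects_six_genes(self):
        sig = reference_significance_pattern()
        genes = select_genes_for_ia(sig, min_components=3,
                                    exclude_treatments=("ToxMix",))
        assert set(genes) == set(MODELED_GENES)
        assert len(genes) == 6

    def test_two_component_gene_excluded(self):
        sig = reference_significance_pattern()
        genes = select_genes_for_ia(sig, min_components=3,
                                    exclude_treatments=("ToxMix",))
        assert "TJP2" not in genes  # significant for only two components
        assert "GJA1" not in genes  # significant for none

    def test_mixture_does_not_count_toward_components(self):
        sig = pd.DataFrame(
            [
                {"gene": "g", "treatment": t, "rel_conc": 0.1,
                 "p_adj": 0.01, "significant": True}
                for t in ("a", "b", "Mix")
            ]
        )
        assert select_genes_for_ia(sig, 3, exclude_treatments=("Mix",)) == []
        assert select_genes_for_ia(sig, 3) == ["g"]

    def test_selection_idempotent(self):
        sig = reference_significance_pattern()
        first = select_genes_for_ia(sig, 3, exclude_treatments=("ToxMix",))
        again = select_genes_for_ia(
            sig[sig["gene"].isin(first)], 3, exclude_treatments=("ToxMix",)
        )
        assert first == again


def test_response_csv_roundtrip_uses_percent(tmp_path):
    df = _response({0.0: [0.1, -0.1], 0.005: [0.5, 0.4]})
    path = tmp_path / "r.csv"
    write_response_csv(df, path)
    header = path.read_text().splitlines()[0]
    assert "rel_conc_percent" in header
    back = read_response_csv(path)
    np.testing.assert_allclose(
        np.sort(back["rel_conc"].unique()), [0.0, 0.005], atol=1e-12
    )
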