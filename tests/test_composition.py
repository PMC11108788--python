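"""Composition GLMM: oracle limits, LTSR, effect centering, neighborhoods."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi
from hypothesis import given, settings, strategies as st

from myoaging import composition as comp, simulate as sim


def _fit_table(truth, seed):
    table, meta = sim.simulate_composition(truth, seed)
    return comp.make_composition_table(table, meta)


class TestMakeTable:
    def test_zero_pairs_materialized(self, small_composition_truth):
        table, meta = sim.simulate_composition(small_composition_truth, 4)
        dropped = table[table["count"] > 0].copy()
        full = comp.make_composition_table(dropped, meta)
        assert len(full) == len(small_composition_truth.cell_types) * len(meta)
        assert (full["count"] >= 0).all()

    def test_duplicate_pair_rejected(self, small_composition_truth):
        table, meta = sim.simulate_composition(small_composition_truth, 4)
        dup = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            comp.make_composition_table(dup, meta)


class TestGLMLimit:
    def test_pinned_variances_match_poisson_glm(self, small_composition_truth):
        """With every variance component pinned at zero the fit is the
        ordinary Poisson GLM MLE (independent statsmodels oracle)."""
        t = _fit_table(small_composition_truth, 7)
        fit = comp.fit_composition_glmm(
            t, comp.ModelSpec(pinned=comp.DEFAULT_TERMS)
        )
        lib_ages = t.drop_duplicates("sample")["age_years"].to_numpy()
        z = (t["age_years"].to_numpy() - lib_ages.mean()) / lib_ages.std()
        X = np.column_stack([np.ones(len(t)), z])
        oracle = smapi.GLM(
            t["count"].to_numpy(), X, family=smapi.families.Poisson()
        ).fit()
        np.testing.assert_allclose(fit.glmm.beta, oracle.params, rtol=1e-4)


class TestLTSR:
    @pytest.mark.parametrize(
        "mean,sd,expect,tol",
        [(0.0, 1.0, 0.5, 1e-12), (1.96, 1.0, 0.9750, 1e-4), (-3.0, 1.0, 0.99865, 1e-5)],
    )
    def test_reference_values(self, mean, sd, expect, tol):
        assert comp.compute_ltsr(mean, sd) == pytest.approx(expect, abs=tol)

    def test_nonpositive_sd_errors(self):
        with pytest.raises(ValueError):
            comp.compute_ltsr(1.0, 0.0)

    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5), sd=st.floats(0.01, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_effect_size_and_bounded(self, m1, m2, sd):
        l1, l2 = comp.compute_ltsr(m1, sd), comp.compute_ltsr(m2, sd)
        assert 0.5 <= l1 <= 1.0
        if abs(m1) <= abs(m2):
            assert l1 <= l2 + 1e-12


class TestAgeEffects:
    def test_recovery_of_planted_effect(self):
        rng = np.random.default_rng(3)
        cts = [f"CT{i}" for i in range(6)]
        truth = sim.CompositionTruth(
            cell_types=cts,
            n_donors=20,
            ages=[float(a) for a in np.concatenate(
                [rng.uniform(20, 40, 10), rng.uniform(60, 75, 10)]
            )],
            baseline_log_abundance={c: np.log(200.0) for c in cts},
            age_logfc={"CT0": 1.0},
            re_sd={"sample": 0.1, "modality": 0.2, "sample_celltype": 0.1},
        )
        fit = comp.fit_composition_glmm(_fit_table(truth, 19))
        eff = comp.celltype_age_effects(fit)
        planted = eff.set_index("cell_type").loc["CT0"]
        assert abs(planted["logfc"] - 1.0) < 0.3
        assert planted["ltsr"] > 0.9
        others = eff[eff["cell_type"] != "CT0"]
        assert (others["ltsr"] < 0.9).all()
        # grand mean over cell types equals the shared fixed age slope
        assert eff["logfc"].mean() == pytest.approx(fit.glmm.beta[1], abs=1e-9)

    def test_centering_symmetry_two_types(self):
        """With two cell types the centered effects are symmetric about
        the shared fixed term."""
        rng = np.random.default_rng(5)
        truth = sim.CompositionTruth(
            cell_types=["up", "down"],
            n_donors=12,
            ages=[float(a) for a in np.concatenate(
                [rng.uniform(20, 40, 6), rng.uniform(60, 75, 6)]
            )],
            baseline_log_abundance={"up": np.log(150.0), "down": np.log(150.0)},
            age_logfc={"up": 0.6, "down": -0.6},
        )
        fit = comp.fit_composition_glmm(_fit_table(truth, 23))
        eff = comp.celltype_age_effects(fit).set_index("cell_type")
        shared = fit.glmm.beta[1]
        assert eff.loc["up", "logfc"] - shared == pytest.approx(
            shared - eff.loc["down", "logfc"], abs=1e-9
        )

    def test_all_zero_celltype_warns_but_fits(self, small_composition_truth):
        t = _fit_table(small_composition_truth, 31)
        t.loc[t["cell_type"] == "CT4", "count"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            fit = comp.fit_composition_glmm(t)
        assert len(comp.celltype_age_effects(fit)) == 5


class TestPermutationSanity:
    def test_shuffled_ages_collapse_the_planted_effect(self):
        """Permuting donor ages leaves only chance correlation: the
        estimated effect for the planted cell type collapses (a permuted
        age vector correlates with a fixed donor pattern with sd
        1/sqrt(n_donors - 1) ~ 0.23, so the permuted median |logfc| must
        sit far below the planted 1.0), while matched unpermuted fits
        recover it confidently."""
        rng = np.random.default_rng(77)
        cts = [f"CT{i}" for i in range(5)]
        ages = np.concatenate([rng.uniform(20, 40, 8), rng.uniform(60, 75, 8)])
        perm_effects = []
        true_ltsr = []
        n_rep = 4
        for rep in range(n_rep):
            truth = sim.CompositionTruth(
                cell_types=cts,
                n_donors=16,
                ages=[float(a) for a in ages],
                baseline_log_abundance={c: np.log(150.0) for c in cts},
                age_logfc={"CT0": 1.0},
                re_sd={"sample": 0.1},
            )
            table, meta = sim.simulate_composition(truth, 100 + rep)
            t_true = comp.make_composition_table(table, meta)
            eff_true = comp.celltype_age_effects(
                comp.fit_composition_glmm(t_true)
            ).set_index("cell_type")
            true_ltsr.append(eff_true.loc["CT0", "ltsr"])

            # shuffle ages across donors after generation
            meta_perm = meta.copy()
            age_map = dict(zip(meta["donor"].unique(), rng.permutation(ages)))
            meta_perm["age_years"] = meta_perm["donor"].map(age_map)
            t_perm = comp.make_composition_table(table, meta_perm)
            eff_perm = comp.celltype_age_effects(
                comp.fit_composition_glmm(t_perm)
            ).set_index("cell_type")
            perm_effects.append(abs(eff_perm.loc["CT0", "logfc"]))
        assert all(lt > 0.9 for lt in true_ltsr)
        assert np.median(perm_effects) < 0.5


class TestNeighborhoodLabels:
    def _frames(self, ct_rows, donor_rows):
        idx = [f"nb{i}" for i in range(len(ct_rows))]
        ct = pd.DataFrame(ct_rows, index=idx, columns=["T", "U"])
        dn = pd.DataFrame(donor_rows, index=idx, columns=["d1", "d2"])
        return ct, dn

    def test_rules(self):
        ct, dn = self._frames(
            [[65, 35], [80, 20], [80, 20]],
            [[50, 50], [95, 5], [50, 50]],
        )
        out = comp.label_neighborhoods(ct, dn)
        assert out.loc["nb0", "label"] == "mixed" and not out.loc["nb0", "keep"]
        assert out.loc["nb1", "label"] == "Donor-specific" and not out.loc["nb1", "keep"]
        assert out.loc["nb2", "label"] == "T" and out.loc["nb2", "keep"]

    def test_boundaries(self):
        # exactly 70% majority is kept; exactly 90% donor share is kept
        ct, dn = self._frames([[70, 30]], [[90, 10]])
        out = comp.label_neighborhoods(ct, dn)
        assert out.loc["nb0", "label"] == "T" and out.loc["nb0", "keep"]

    def test_misaligned_rows_error(self):
        ct, dn = self._frames([[70, 30]], [[90, 10]])
        dn.index = ["other"]
        with pytest.raises(ValueError, match="misaligned"):
            comp.label_neighborhoods(ct, dn)

    def test_zero_row_error(self):
        ct, dn = self._frames([[0, 0]], [[1, 1]])
        with pytest.raises(ValueError, match="positive"):
            comp.label_neighborhoods(ct, dn)
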