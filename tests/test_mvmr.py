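"""Multivariable MR: assembly bookkeeping and the joint IVW fit."""

import numpy as np
import pytest

from mrpipe.estimators import InsufficientInstrumentsError, ivw
from mrpipe.mvmr import MVMRInput, assemble_mvmr, mvmr_ivw
from mrpipe.simulate import SyntheticTruth, generate_study

from conftest import make_harmonized, make_table


def _mv_input(rng, k=20, m=2, theta=(0.2, -0.1)):
    bx = rng.uniform(0.05, 0.3, size=(k, m)) * rng.choice([-1, 1], size=(k, m))
    sx = np.full((k, m), 0.01)
    sy = rng.uniform(0.01, 0.04, k)
    by = bx @ np.asarray(theta[:m]) + rng.normal(0, sy)
    return MVMRInput(
        variant_ids=[f"rs{i}" for i in range(k)],
        beta_x_matrix=bx,
        se_x_matrix=sx,
        beta_y=by,
        se_y=sy,
        exposure_labels=[f"exp{j}" for j in range(m)],
    )


class TestAssembly:
    def _tables(self):
        exp1 = make_table(
            [("rs1", "A", "G", 0.3, 0.10, 0.01, 1e-10, 10000),
             ("rs2", "T", "C", 0.2, 0.12, 0.01, 1e-12, 10000),
             ("rs3", "G", "A", 0.4, 0.08, 0.01, 1e-9, 10000),
             ("rs4", "A", "C", 0.25, 0.01, 0.01, 0.5, 10000)],
            trait="e1",
        )
        exp2 = make_table(
            [("rs1", "A", "G", 0.3, 0.02, 0.01, 0.5, 10000),
             ("rs2", "T", "C", 0.2, 0.01, 0.01, 0.5, 10000),
             ("rs3", "G", "A", 0.4, 0.03, 0.01, 0.5, 10000),
             ("rs4", "A", "C", 0.25, 0.15, 0.01, 1e-15, 10000)],
            trait="e2",
        )
        outcome = make_table(
            [("rs1", "A", "G", 0.3, 0.05, 0.02, 0.5, 20000),
             ("rs2", "C", "T", 0.8, -0.04, 0.02, 0.5, 20000),  # swapped alleles
             ("rs3", "G", "A", 0.4, 0.01, 0.02, 0.5, 20000),
             ("rs4", "A", "C", 0.25, 0.06, 0.02, 0.5, 20000)],
            trait="y",
        )
        return exp1, exp2, outcome

    def test_union_and_allele_alignment(self):
        exp1, exp2, outcome = self._tables()
        inp = assemble_mvmr([exp1, exp2], outcome)
        assert set(inp.variant_ids) == {"rs1", "rs2", "rs3", "rs4"}
        assert inp.m == 2
        i = inp.variant_ids.index("rs2")
        # outcome rs2 was reported on the swapped allele: sign must flip
        assert inp.beta_y[i] == pytest.approx(0.04)

    def test_variant_missing_from_one_exposure_dropped(self):
        exp1, exp2, outcome = self._tables()
        exp2_missing = make_table(
            [tuple(r) for r in exp2.df.itertuples(index=False)][1:], trait="e2"
        )
        inp = assemble_mvmr([exp1, exp2_missing], outcome)
        assert "rs1" not in inp.variant_ids
        assert ("rs1", "missing_in_exposure") in inp.dropped
        assert set(inp.variant_ids) == {"rs2", "rs3", "rs4"}

    def test_underdetermined_system_is_error(self):
        exp1, exp2, outcome = self._tables()
        small1 = make_table([tuple(exp1.df.iloc[0])], trait="e1")
        small2 = make_table([tuple(exp2.df.iloc[3])], trait="e2")
        with pytest.raises(ValueError, match="underdetermined"):
            assemble_mvmr([small1, small2], outcome)


class TestFit:
    def test_single_exposure_reduces_to_ivw(self, rng):
        inp = _mv_input(rng, m=1, theta=(0.25,))
        h = make_harmonized(
            inp.beta_x_matrix[:, 0], inp.se_x_matrix[:, 0], inp.beta_y, inp.se_y
        )
        uni = ivw(h)
        mv = mvmr_ivw(inp)[0]
        assert mv.beta == pytest.approx(uni.beta, abs=1e-10)
        assert mv.se == pytest.approx(uni.se, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        import statsmodels.api as sm

        inp = _mv_input(rng, k=30, m=3, theta=(0.2, -0.1, 0.05))
        fit = sm.WLS(inp.beta_y, inp.beta_x_matrix, weights=1.0 / inp.se_y**2).fit()
        ests = mvmr_ivw(inp)
        for j, est in enumerate(ests):
            assert est.beta == pytest.approx(fit.params[j], abs=1e-10)

    def test_duplicated_exposure_column_raises_collinearity(self, rng):
        inp = _mv_input(rng, m=2)
        inp.beta_x_matrix[:, 1] = inp.beta_x_matrix[:, 0]
        with pytest.raises(InsufficientInstrumentsError, match="collinear"):
            mvmr_ivw(inp)

    def test_conditional_f_reported(self, rng):
        ests = mvmr_ivw(_mv_input(rng, k=40, m=2))
        assert all(e.conditional_f is not None and e.conditional_f > 0 for e in ests)

    def test_mediated_coexposure_attenuates_toward_zero(self):
        """An exposure whose apparent effect flows wholly through a correlated
        co-exposure should shrink toward zero once that co-exposure is in the
        model (sign test over replicates)."""
        reps = 120
        uni_hits = 0
        mv_closer = 0
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            k = 40
            g1 = rng.uniform(0.05, 0.2, k)   # instruments of exposure 1
            g2 = rng.uniform(0.05, 0.2, k)   # instruments of exposure 2
            lam = 0.6                         # exposure 2 -> exposure 1 loading
            bx1 = np.concatenate([g1, lam * g2]) + rng.normal(0, 0.005, 2 * k)
            bx2 = np.concatenate([np.zeros(k), g2]) + rng.normal(0, 0.005, 2 * k)
            theta1 = 0.25                     # only exposure 1 is causal
            sy = np.full(2 * k, 0.01)
            by = theta1 * np.concatenate([g1, lam * g2]) + rng.normal(0, sy)
            inp = MVMRInput(
                variant_ids=[f"rs{i}" for i in range(2 * k)],
                beta_x_matrix=np.column_stack([bx1, bx2]),
                se_x_matrix=np.full((2 * k, 2), 0.005),
                beta_y=by,
                se_y=sy,
                exposure_labels=["e1", "e2"],
            )
            h2 = make_harmonized(bx2[k:], [0.005] * k, by[k:], sy[k:])
            uni2 = ivw(h2)
            mv2 = mvmr_ivw(inp)[1]
            if uni2.pval < 0.05:
                uni_hits += 1
            if abs(mv2.beta) < abs(uni2.beta):
                mv_closer += 1
        assert uni_hits > 0.9 * reps      # univariable sees a spurious effect
        assert mv_closer > 0.9 * reps     # MVMR attenuates it toward zero


class TestAssemblyFromGenerator:
    def test_mediator_chain_recovers_direct_effects(self):
        truth = SyntheticTruth(
            mediation=True, delta=0.5, tau=0.2, theta_dir=0.1, k=40, k_med=40, seed=3
        )
        study = generate_study(truth)
        inp = assemble_mvmr([study.exposure, study.mediator], study.outcome(1))
        ests = mvmr_ivw(inp)
        by_label = {e.exposure_label: e for e in ests}
        assert by_label["X"].beta == pytest.approx(0.1, abs=4 * by_label["X"].se)
        assert by_label["M"].beta == pytest.approx(0.2, abs=4 * by_label["M"].se)
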