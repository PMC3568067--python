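"""Simplex-grid composition enumeration and batch scanning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiocore import coregen, fba, grid
from cardiocore.grid import Composition, ScanConfig, enumerate_compositions, run_scan

FOUR = [coregen.uptake_id(n) for n in ["glucose", "oleate", "acetoacetate", "lactate"]]


def four_substrate_config(step=0.25, **kw):
    return ScanConfig(uptake_ids=FOUR, oxygen_id="EX_o2", step=step,
                      target_fluxes={coregen.ATPASE: 21.6}, **kw)


class TestComposition:
    def test_sum_must_be_one(self):
        with pytest.raises(ValueError):
            Composition({"a": 0.5, "b": 0.4})

    def test_betas_must_be_in_unit_interval(self):
        with pytest.raises(ValueError):
            Composition({"a": 1.5, "b": -0.5})


class TestEnumeration:
    def test_two_substrates_half_step(self):
        comps = enumerate_compositions(2, 0.5)
        assert [tuple(c.as_dict().values()) for c in comps] == [
            (0.0, 1.0), (0.5, 0.5), (1.0, 0.0)]

    def test_three_substrates_quarter_step(self):
        # brute force: all (i,j,k) with i+j+k = 4 -> C(6,2) = 15
        brute = {(i / 4, j / 4, (4 - i - j) / 4)
                 for i in range(5) for j in range(5 - i)}
        comps = enumerate_compositions(3, 0.25)
        assert len(comps) == 15
        assert {tuple(c.as_dict().values()) for c in comps} == brute

    def test_lexicographic_order(self):
        comps = enumerate_compositions(3, 0.5)
        vecs = [tuple(c.as_dict().values()) for c in comps]
        assert vecs == sorted(vecs)

    def test_non_integral_step_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compositions(3, 0.3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=6), st.integers(min_value=1, max_value=12))
    def test_count_law(self, n, k):
        comps = enumerate_compositions(n, 1.0 / k)
        assert len(comps) == math.comb(k + n - 1, n - 1)
        assert len(comps) == grid.composition_count(n, 1.0 / k)
        for c in comps:
            assert sum(c.as_dict().values()) == pytest.approx(1.0, abs=1e-12)


class TestApplyComposition:
    def test_exclusive_first_substrate(self, core_problem):
        comp = Composition(dict(zip(FOUR, [1.0, 0.0, 0.0, 0.0])))
        dist = fba.minimize_uptake(grid.apply_composition(core_problem, comp))
        for rid in FOUR[1:]:
            assert abs(dist.fluxes[rid]) <= 1e-9

    def test_uptake_ratio_follows_betas(self, core_problem):
        comp = Composition(dict(zip(FOUR, [0.79, 0.21, 0.0, 0.0])))
        dist = fba.minimize_uptake(grid.apply_composition(core_problem, comp))
        assert dist.fluxes["EX_glucose"] / dist.fluxes["EX_oleate"] == pytest.approx(
            79 / 21, rel=1e-6)

    def test_random_betas_satisfy_coupling(self, core_problem, rng):
        for _ in range(20):
            b = rng.dirichlet(np.ones(4))
            comp = Composition(dict(zip(FOUR, b / b.sum())))
            dist = fba.minimize_uptake(grid.apply_composition(core_problem, comp))
            for rid, beta in comp.as_dict().items():
                assert dist.fluxes[rid] / dist.v_s == pytest.approx(beta, abs=1e-8)

    def test_unknown_uptake_rejected(self, core_problem):
        with pytest.raises(KeyError):
            grid.apply_composition(core_problem, Composition({"EX_nope": 1.0}))


class TestRunScan:
    def test_four_substrate_quarter_grid(self, core_network):
        res = run_scan(core_network, four_substrate_config())
        assert len(res.frame) == 35  # C(7,3)
        assert (res.frame["status"] == "optimal").all()
        # v_s bounded by demand over extreme yields (oleate 134, lactate 17)
        assert (res.frame["vs"] >= 21.6 / 134 - 1e-9).all()
        assert (res.frame["vs"] <= 21.6 / 17 + 1e-9).all()

    def test_exclusive_rows_match_closed_form(self, core_network):
        res = run_scan(core_network, four_substrate_config())
        f = res.frame
        glc = f[f["beta_EX_glucose"] == 1.0].iloc[0]
        assert glc["vs"] == pytest.approx(0.6, abs=1e-8)
        assert glc["vO2"] == pytest.approx(3.6, abs=1e-8)
        ole = f[f["beta_EX_oleate"] == 1.0].iloc[0]
        assert ole["vO2"] == pytest.approx(21.6 / 134 * 25.5, abs=1e-8)

    def test_single_composition_equals_direct_solve(self, core_network, core_problem):
        comp = Composition(dict(zip(FOUR, [0.25, 0.25, 0.25, 0.25])))
        cfg = ScanConfig(uptake_ids=FOUR, oxygen_id="EX_o2", compositions=[comp],
                         target_fluxes={coregen.ATPASE: 21.6})
        res = run_scan(core_network, cfg)
        direct = fba.minimize_uptake(fba.with_composition(core_problem, comp.as_dict()))
        assert res.frame.iloc[0]["vs"] == pytest.approx(direct.v_s, rel=1e-9)
        assert res.frame.iloc[0]["vO2"] == pytest.approx(direct.v_O2, rel=1e-9)

    def test_infeasible_rows_recorded_not_dropped(self):
        opts = coregen.CoreOptions(include_lipid_targets=True)
        net = coregen.build_core_network(options=opts)
        ids = [coregen.uptake_id(n) for n in ["glucose", "alpha_linoleate", "dha"]]
        cfg = ScanConfig(
            uptake_ids=ids, oxygen_id="EX_o2", step=0.5,
            target_fluxes={coregen.ATPASE: 21.6,
                           **{f"DEMAND_{t}": v
                              for t, v in coregen.DEFAULT_LIPID_TARGET_FLUXES.items()}},
        )
        res = run_scan(net, cfg)
        assert len(res.frame) == 6
        statuses = res.frame["status"]
        # rows lacking an essential fatty acid are infeasible but present
        assert (statuses == "infeasible").any()
        assert (statuses == "optimal").any()

    def test_checkpoint_resume_completes_identically(self, core_network, tmp_path):
        ckpt = tmp_path / "scan.tsv"
        cfg = four_substrate_config(checkpoint=ckpt, checkpoint_every=10)
        full = run_scan(core_network, four_substrate_config())
        partial = run_scan(core_network, cfg)
        # simulate a kill: truncate the checkpoint to the first flush
        import pandas as pd

        done = pd.read_csv(ckpt, sep="\t").iloc[:10]
        done.to_csv(ckpt, sep="\t", index=False, float_format="%.10g")
        resumed = run_scan(core_network, cfg)
        assert len(resumed.frame) == len(full.frame)
        np.testing.assert_allclose(resumed.frame["vs"], full.frame["vs"], rtol=1e-9)

    def test_permutation_invariance(self, core_network, rng):
        comps = enumerate_compositions(4, 0.5, FOUR)
        perm = list(rng.permutation(len(comps)))
        cfg_a = ScanConfig(uptake_ids=FOUR, oxygen_id="EX_o2", compositions=comps,
                           target_fluxes={coregen.ATPASE: 21.6})
        cfg_b = ScanConfig(uptake_ids=FOUR, oxygen_id="EX_o2",
                           compositions=[comps[i] for i in perm],
                           target_fluxes={coregen.ATPASE: 21.6})
        a = run_scan(core_network, cfg_a).frame
        b = run_scan(core_network, cfg_b).frame
        for row_b, i in zip(b.itertuples(index=False), perm):
            row_a = a.iloc[i]
            assert row_b.vs == pytest.approx(row_a["vs"], rel=1e-9)
            assert row_b.vO2 == pytest.approx(row_a["vO2"], rel=1e-9)
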