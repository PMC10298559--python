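import math
import subprocess

import numpy as np
import pytest

from _oracles import ancestral_bm_oracle
from tehorizon.datasets import noctuid_te_loads
from tehorizon.phylo_comparative import (MODELS, ModelFit, TraitTree,
                                         ancestral_ml, blomberg_k, eb_cov,
                                         fit_continuous, pagel_lambda,
                                         pearson_correlation,
                                         _profiled_loglik)
from tehorizon.synthetic_data import simulate_trait
from tehorizon.timetree import TimeTree


class TestPearson:
    def test_te_class_correlations_from_published_loads(self):
        df = noctuid_te_loads()
        line = pearson_correlation(df.line_pct, df.genome_size_mb)
        dna = pearson_correlation(df.dte_pct, df.genome_size_mb)
        assert round(line.r, 2) == 0.83
        assert round(dna.r, 2) == 0.81
        assert line.p_value < 0.005 and dna.p_value < 0.005

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12


class TestPagelLambda:
    def test_bm_trait_has_high_lambda(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=101)[0]
        res = pagel_lambda(TraitTree(tree64, trait))
        assert res.estimate >= 0.9
        assert res.p_value < 0.05

    def test_permuted_trait_has_low_lambda(self, tree64, rng):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=101)[0]
        vals = rng.permutation(list(trait.values()))
        res = pagel_lambda(TraitTree(tree64, dict(zip(trait, vals))))
        assert res.estimate < 0.2

    def test_star_tree_degenerate(self):
        tree = TimeTree("(A:1,B:1,C:1,D:1);")
        res = pagel_lambda(TraitTree(tree, {"A": 0.0, "B": 1.0,
                                            "C": 2.0, "D": 3.0}))
        assert res.degenerate

    def test_lambda_one_likelihood_equals_bm(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=7)[0]
        tt = TraitTree(tree64, trait)
        l_bm = _profiled_loglik(tt.z, tt.C)[0]
        C1 = tt.C.copy()
        assert _profiled_loglik(tt.z, C1)[0] == pytest.approx(l_bm)
        # lambda = 0 equals the heteroscedastic-diagonal likelihood
        l0 = _profiled_loglik(tt.z, np.diag(np.diag(tt.C)))[0]
        res = pagel_lambda(tt)
        assert res.log_likelihood_null == pytest.approx(l0)


class TestBlombergK:
    def test_bm_traits_give_k_near_one(self, tree64):
        traits = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                                seed=5, n_reps=50)
        ks = [blomberg_k(TraitTree(tree64, t), n_perm=0).estimate
              for t in traits]
        assert 0.85 <= np.mean(ks) <= 1.15

    def test_permutation_destroys_signal(self, tree64, rng):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=13)[0]
        tt = TraitTree(tree64, trait)
        k_obs = blomberg_k(tt, n_perm=199, seed=1)
        vals = rng.permutation(list(trait.values()))
        k_perm = blomberg_k(TraitTree(tree64, dict(zip(trait, vals))),
                            n_perm=199, seed=1)
        assert k_perm.estimate < k_obs.estimate
        assert k_obs.p_value < 0.05 < k_perm.p_value

    def test_no_permutations_no_pvalue(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=5)[0]
        res = blomberg_k(TraitTree(tree64, trait), n_perm=0)
        assert res.p_value is None and res.n_permutations == 0


class TestFitContinuous:
    def test_eb_limit_reproduces_bm(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 2.0, "z0": 1.0},
                               seed=3)[0]
        tt = TraitTree(tree64, trait)
        l_bm = fit_continuous(tt, "BM").log_likelihood
        l_eb_limit = _profiled_loglik(tt.z, eb_cov(tt.C, -1e-8))[0]
        assert l_eb_limit == pytest.approx(l_bm, abs=1e-6)

    def test_wn_equals_iid_normal_closed_form(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=9)[0]
        tt = TraitTree(tree64, trait)
        fit = fit_continuous(tt, "WN")
        z = tt.z
        s2 = np.mean((z - z.mean()) ** 2)
        logl = -0.5 * len(z) * (math.log(2 * math.pi * s2) + 1)
        assert fit.log_likelihood == pytest.approx(logl, abs=1e-8)
        assert fit.parameters["z0"] == pytest.approx(z.mean())

    def test_eb_traits_select_eb_by_aicc(self, tree64):
        traits = simulate_trait(tree64, "EB",
                                {"sigma2": 1.0, "z0": 0.0, "a": -0.05},
                                seed=21, n_reps=20)
        mean_aicc = {m: np.mean([fit_continuous(TraitTree(tree64, t),
                                                m).aicc for t in traits])
                     for m in MODELS}
        assert min(mean_aicc, key=mean_aicc.get) == "EB"

    def test_aicc_ordering_invariant_to_affine_rescale(self, tree64):
        trait = simulate_trait(tree64, "EB",
                               {"sigma2": 1.0, "z0": 0.0, "a": -0.03},
                               seed=2)[0]
        scaled = {k: 7.0 * v + 100.0 for k, v in trait.items()}
        for models in (("BM", "EB", "WN"),):
            a1 = [fit_continuous(TraitTree(tree64, trait), m).aicc
                  for m in models]
            a2 = [fit_continuous(TraitTree(tree64, scaled), m).aicc
                  for m in models]
            assert np.argsort(a1).tolist() == np.argsort(a2).tolist()

    def test_aicc_formula(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=4)[0]
        fit = fit_continuous(TraitTree(tree64, trait), "BM")
        n, k = fit.n, fit.k_params
        assert fit.aicc == pytest.approx(
            -2 * fit.log_likelihood + 2 * k + 2 * k * (k + 1) / (n - k - 1))


class TestAncestral:
    def _bm_fit(self, tt):
        return fit_continuous(tt, "BM")

    def test_two_tip_symmetry(self):
        tree = TimeTree("(A:1,B:1);")
        tt = TraitTree(tree, {"A": 0.0, "B": 10.0})
        fit = ModelFit(model="BM", parameters={"sigma2": 1.0, "z0": 0.0},
                       log_likelihood=0.0, k_params=2, aicc=0.0, n=2)
        anc = ancestral_ml(tt, fit)
        assert anc.states["n0"] == pytest.approx(5.0)

    def test_three_tip_matches_joint_likelihood_oracle(self):
        tree = TimeTree("((A:1,B:1):1,C:2);")
        tt = TraitTree(tree, {"A": 0.0, "B": 0.0, "C": 3.0})
        anc = ancestral_ml(tt, self._bm_fit(tt))
        node_ids, M = tree.node_tip_shared_depths()
        node_cov = np.array([[0.0, 0.0], [0.0, 1.0]])  # root, mrca(A,B)
        oracle = ancestral_bm_oracle(tt.C, M, node_cov, tt.z)
        for nid, want in zip(node_ids, oracle):
            assert anc.states[nid] == pytest.approx(want, abs=1e-4)

    def test_constant_trait_all_no_change(self, tree64):
        tt = TraitTree(tree64, {t: 4.2 for t in tree64.taxa})
        anc = ancestral_ml(tt, ModelFit(
            model="BM", parameters={"sigma2": 1.0, "z0": 4.2},
            log_likelihood=0.0, k_params=2, aicc=0.0, n=tree64.n_tips))
        assert all(v == pytest.approx(4.2) for v in anc.states.values())
        assert {d for _, _, d in anc.directions} == {"no_change"}

    def test_directions_match_state_differences(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=6)[0]
        tt = TraitTree(tree64, trait)
        anc = ancestral_ml(tt, self._bm_fit(tt))
        value = dict(anc.states)
        value.update(trait)
        for parent, child, direction in anc.directions:
            delta = value[child] - value[parent]
            assert direction == ("expansion" if delta > 0 else "reduction")

    def test_root_state_equals_phylogenetic_mean(self, tree64):
        trait = simulate_trait(tree64, "BM", {"sigma2": 1.0, "z0": 0.0},
                               seed=8)[0]
        tt = TraitTree(tree64, trait)
        anc = ancestral_ml(tt, self._bm_fit(tt))
        Cinv = np.linalg.inv(tt.C)
        ones = np.ones(tt.n)
        abar = float(ones @ Cinv @ tt.z) / float(ones @ Cinv @ ones)
        assert anc.states["n0"] == pytest.approx(abar)

    def test_states_invariant_to_tip_order(self):
        orth = {"A": 1.0, "B": 2.0, "C": 5.0}
        t1 = TimeTree("((A:1,B:1):1,C:2);")
        t2 = TimeTree("(C:2,(B:1,A:1):1);")
        f1 = fit_continuous(TraitTree(t1, orth), "BM")
        a1 = ancestral_ml(TraitTree(t1, orth), f1)
        f2 = fit_continuous(TraitTree(t2, orth), "BM")
        a2 = ancestral_ml(TraitTree(t2, orth), f2)
        by_clade1 = {a1.clades[n]: v for n, v in a1.states.items()}
        by_clade2 = {a2.clades[n]: v for n, v in a2.states.items()}
        assert set(by_clade1) == set(by_clade2)
        for clade, v in by_clade1.items():
            assert by_clade2[clade] == pytest.approx(v)


class TestAgainstPhytools:
    """Independent oracle: the reference R implementation of the signal
    statistics on a fixed small tree/trait."""

    def test_lambda_and_k_match_reference(self, tmp_path):
        from tehorizon.synthetic_data import random_ultrametric_newick
        nwk = random_ultrametric_newick(10, 100.0, seed=5)
        tree = TimeTree(nwk)
        trait = simulate_trait(tree, "BM", {"sigma2": 0.5, "z0": 2.0},
                               seed=11)[0]
        tt = TraitTree(tree, trait)
        lam = pagel_lambda(tt)
        kk = blomberg_k(tt, n_perm=0)

        (tmp_path / "tree.nwk").write_text(nwk + "\n")
        with open(tmp_path / "trait.csv", "w") as fh:
            for k, v in trait.items():
                fh.write(f"{k},{v!r}\n")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(phytools))\n'
            f'tree <- read.tree("{tmp_path}/tree.nwk")\n'
            f'd <- read.csv("{tmp_path}/trait.csv", header=FALSE)\n'
            'x <- setNames(d$V2, d$V1)\n'
            'l <- phylosig(tree, x, method="lambda")\n'
            'k <- phylosig(tree, x, method="K")\n'
            'cat(sprintf("%.8f %.8f %.8f", l$lambda, l$logL, k))\n')
        out = subprocess.run(["Rscript", str(script)],
                             capture_output=True, text=True, check=True)
        r_lambda, r_logl, r_k = map(float, out.stdout.split())
        assert lam.estimate == pytest.approx(r_lambda, abs=1e-4)
        assert lam.log_likelihood == pytest.approx(r_logl, abs=1e-5)
        assert kk.estimate == pytest.approx(r_k, abs=1e-6)
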