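"""Pruning likelihood: rescaling, tip vectors, oracle equivalence, priors."""

import math

import numpy as np
import pytest

import karyorate as kr
from karyorate.likelihood import (
    MissingTipDataError,
    TipObservation,
    forward_transform_rates,
    log_posterior,
    log_prior,
    pruning_loglik,
    rescale_to_unit_height,
    tip_vector,
)
from karyorate.statespace import build_rate_matrix

from helpers import enumeration_loglik, random_instance


class TestRescaling:
    def test_cherry_rescales_to_unit_height(self, cherry):
        unit, scale = rescale_to_unit_height(cherry)
        assert scale == 50.0
        assert unit.height == pytest.approx(1.0, abs=1e-9)

    def test_unit_tree_unchanged(self):
        tree = kr.Phylogeny.from_newick("(a:1,b:1);")
        unit, scale = rescale_to_unit_height(tree)
        assert scale == 1.0
        assert np.allclose(unit.brlen, tree.brlen)

    def test_balanced_tree_depths(self, rng):
        tree = kr.simulate_yule_tree(4, 1.0, rng, height_target=120.0)
        unit, scale = rescale_to_unit_height(tree)
        assert scale == pytest.approx(120.0)
        assert np.allclose(unit.tip_depths(), 1.0, atol=1e-9)

    def test_non_ultrametric_rejected_unless_overridden(self):
        tree = kr.Phylogeny.from_newick("(a:1,b:2);")
        with pytest.raises(ValueError):
            rescale_to_unit_height(tree)
        unit, scale = rescale_to_unit_height(tree, allow_non_ultrametric=True)
        assert scale == 2.0


class TestBackTransform:
    def test_division_by_height(self):
        p = kr.RateParameters(gamma_H=5.0)
        out = kr.back_transform_rates(p, 100.0)
        assert out.gamma_H == pytest.approx(0.05)
        assert out.units == "per_Myr"

    def test_scale_one_is_identity(self):
        p = kr.RateParameters(gamma_M=1.2, q_HM=0.3)
        out = kr.back_transform_rates(p, 1.0)
        assert out.as_array() == pytest.approx(p.as_array())

    def test_round_trip(self):
        p = kr.RateParameters(*np.linspace(0.1, 0.8, 8))
        back = forward_transform_rates(kr.back_transform_rates(p, 37.5), 37.5)
        assert back.as_array() == pytest.approx(p.as_array(), abs=1e-12)

    def test_invalid_scale(self):
        with pytest.raises(ValueError):
            kr.back_transform_rates(kr.RateParameters(), 0.0)


class TestTipVector:
    def test_indicator_positions(self, small_space):
        v = tip_vector(TipObservation("x", 2, kr.HOLOCENTRIC), small_space)
        assert v[4] == 1.0 and v.sum() == 1.0
        v = tip_vector(TipObservation("x", 1, kr.MONOCENTRIC), small_space)
        assert v[0] == 1.0 and v.sum() == 1.0

    def test_out_of_range_names_taxon(self, small_space):
        with pytest.raises(ValueError, match="Genus_x"):
            tip_vector(TipObservation("Genus_x", 7, kr.MONOCENTRIC), small_space)


class TestPruning:
    def test_identical_tips_zero_rates_flat_root(self, small_space):
        tree = kr.Phylogeny.from_newick("(t1:1,t2:1);")
        Q = build_rate_matrix(kr.RateParameters(), small_space)
        data = {t: TipObservation(t, 2, kr.MONOCENTRIC) for t in ("t1", "t2")}
        ll = pruning_loglik(tree, data, Q, root_mode="flat")
        assert ll == pytest.approx(math.log(1 / small_space.size))

    def test_impossible_data_under_zero_rates(self, small_space):
        tree = kr.Phylogeny.from_newick("(t1:1,t2:1);")
        Q = build_rate_matrix(kr.RateParameters(), small_space)
        data = {
            "t1": TipObservation("t1", 1, kr.MONOCENTRIC),
            "t2": TipObservation("t2", 3, kr.MONOCENTRIC),
        }
        assert pruning_loglik(tree, data, Q) == -np.inf

    @pytest.mark.parametrize("root_mode", ["flat", "fitzjohn"])
    def test_matches_enumeration_oracle(self, rng, root_mode):
        for _ in range(20):
            tree, data, Q, space = random_instance(rng, max_tips=5, n_max=4)
            tips = np.array(
                [space.index_of(data[l].haploid_n, data[l].centromere)
                 for l in tree.tip_labels]
            )
            want = enumeration_loglik(tree, tips, Q.entries, root_mode)
            for method in ("uniformization", "expm"):
                got = pruning_loglik(tree, data, Q, root_mode=root_mode, method=method)
                assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_to_tip_relabeling(self, rng):
        tree, data, Q, space = random_instance(rng, max_tips=5, n_max=4)
        base = pruning_loglik(tree, data, Q)
        # swap two labels together with their data
        labs = list(tree.tip_labels)
        perm = {labs[0]: labs[1], labs[1]: labs[0]}
        relabeled = kr.Phylogeny(
            tip_labels=tuple(perm.get(l, l) for l in tree.tip_labels),
            parent=tree.parent.copy(),
            brlen=tree.brlen.copy(),
            children=tree.children,
            postorder=tree.postorder.copy(),
        )
        data2 = {perm.get(k, k): TipObservation(perm.get(k, k), o.haploid_n, o.centromere)
                 for k, o in data.items()}
        assert pruning_loglik(relabeled, data2, Q) == pytest.approx(base, abs=1e-10)

    def test_time_rate_rescaling_identity(self, rng):
        tree, data, Q, space = random_instance(rng, max_tips=5, n_max=4)
        k = 3.7
        base = pruning_loglik(tree, data, Q)
        scaled_tree = tree.with_branch_lengths(tree.brlen / k)
        Qk = kr.RateMatrix(entries=Q.entries * k, statespace=space)
        assert pruning_loglik(scaled_tree, data, Qk) == pytest.approx(base, abs=1e-8)

    def test_unreachable_regime_block_is_inert(self, rng):
        """With no regime switching and all tips monocentric, holocentric
        rates cannot affect the likelihood."""
        tree = kr.simulate_yule_tree(5, 1.0, rng, height_target=1.0)
        space = kr.build_state_space(1, 5)
        data = {l: TipObservation(l, int(rng.integers(1, 6)), kr.MONOCENTRIC)
                for l in tree.tip_labels}
        p1 = kr.RateParameters(gamma_M=1.0, delta_M=0.5)
        p2 = kr.RateParameters(gamma_M=1.0, delta_M=0.5, gamma_H=2.5, delta_H=1.5, rho_H=0.7)
        for method in ("uniformization", "expm"):
            ll1 = pruning_loglik(tree, data, build_rate_matrix(p1, space), method=method)
            ll2 = pruning_loglik(tree, data, build_rate_matrix(p2, space), method=method)
            assert ll1 == pytest.approx(ll2, abs=1e-9)

    def test_missing_tip_data_lists_taxa(self, small_space):
        tree = kr.Phylogeny.from_newick("(t1:1,(t2:0.5,t3:0.5):0.5);")
        Q = build_rate_matrix(kr.RateParameters(), small_space)
        with pytest.raises(MissingTipDataError, match="t2"):
            pruning_loglik(tree, {"t1": TipObservation("t1", 1, kr.MONOCENTRIC)}, Q)


class TestLogPosterior:
    def test_prior_density_at_zero_full_model(self, cherry, small_space, tiny_tip_data):
        lp = log_posterior(
            kr.RateParameters(),
            cherry,
            None,
            small_space,
            prior_rate=0.5,
            loglik_fn=lambda p: 0.0,
        )
        assert lp == pytest.approx(8 * math.log(0.5))

    def test_prior_density_constrained_model(self, cherry, small_space):
        lp = log_posterior(
            kr.RateParameters(),
            cherry,
            None,
            small_space,
            model="no_polyploidy",
            loglik_fn=lambda p: 0.0,
        )
        assert lp == pytest.approx(6 * math.log(0.5))

    def test_prior_term_closed_form(self):
        # Exp(0.5) log-density at rate 2 is ln(0.5) - 1
        assert log_prior(np.array([2.0]), 0.5) == pytest.approx(math.log(0.5) - 1.0)

    def test_negative_parameter_rejected_region(self):
        assert log_prior(np.array([-0.01, 1.0]), 0.5) == -np.inf
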