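"""Affinities, entropy production and balance, GEC, probes, contours,
and the competitive-selectivity identity."""

import numpy as np
import pytest

import nessflow as nf
from nessflow.errors import (
    DomainError,
    ThermodynamicallyIncompleteError,
    UndefinedAffinityError,
    WegscheiderError,
)
from nessflow.network import R_GAS
from nessflow.thermo import gec_point

RT300 = R_GAS * 300.0


class TestAffinities:
    def test_zero_at_pair_equilibrium(self, ab_network):
        # v_f = v_r at [B]/[A] = 2
        Af = nf.affinities(ab_network, np.array([1.0, 2.0]))
        assert Af == pytest.approx([0.0], abs=1e-12)

    def test_rt_ln2_at_unit_composition(self, ab_network):
        Af = nf.affinities(ab_network, np.array([1.0, 1.0]))
        assert Af[0] == pytest.approx(RT300 * np.log(2.0), rel=1e-14)
        assert Af[0] == pytest.approx(1728.85, abs=0.01)  # ~1.729 kJ/mol

    def test_enantiomer_pairs_equal_at_racemic_composition(self,
                                                           frank_network):
        c = np.array([0.5, 0.1, 0.1, 0.2])
        Af = dict(zip(frank_network.pair_ids,
                      nf.affinities(frank_network, c)))
        assert Af["PL"] == pytest.approx(Af["PD"], rel=1e-14)
        assert Af["AL"] == pytest.approx(Af["AD"], rel=1e-14)

    def test_zero_rate_raises_named_error(self, ab_network):
        with pytest.raises(UndefinedAffinityError, match="R1"):
            nf.affinities(ab_network, np.array([1.0, 0.0]))

    def test_irreversible_network_rejected(self):
        net = nf.parse_network(
            "species A init=1.0\nspecies B init=0.0\n"
            "reaction R1: A -> B ; kf=1.0\n")
        with pytest.raises(ThermodynamicallyIncompleteError):
            nf.affinities(net, np.array([1.0, 1.0]))


class TestInternalEntropyProduction:
    def test_zero_at_equilibrium(self, ab_network):
        s = nf.entropy_production_internal(ab_network,
                                           np.array([1.0 / 3, 2.0 / 3]))
        assert abs(s) <= 1e-12 * R_GAS

    def test_hand_value_r_ln2(self, ab_network):
        s = nf.entropy_production_internal(ab_network, np.array([1.0, 1.0]))
        assert s == pytest.approx(R_GAS * np.log(2.0), rel=1e-14)
        assert s == pytest.approx(5.7628, abs=1e-4)

    def test_catalysis_scales_sigma_at_same_affinity(self):
        # x10 both constants: same Keq and affinity, tenfold dissipation
        base = nf.make_ab(2.0, 1.0)
        cat = nf.make_ab(20.0, 10.0)
        c = np.array([1.0, 1.0])
        assert nf.affinities(cat, c)[0] == pytest.approx(
            nf.affinities(base, c)[0], rel=1e-14)
        assert nf.entropy_production_internal(cat, c) == pytest.approx(
            10.0 * nf.entropy_production_internal(base, c), rel=1e-14)

    def test_nonnegative_at_random_compositions(self):
        rng = np.random.default_rng(5)
        for seed in range(8):
            net = nf.random_network(4, 4, driven=bool(seed % 2), seed=seed)
            for _ in range(50):
                c = np.exp(rng.uniform(np.log(0.01), np.log(5.0),
                                       net.n_species))
                assert nf.entropy_production_internal(net, c) >= -1e-12 * R_GAS


class TestRelativePotentialForm:
    def test_hand_example_matches_pairwise_form(self, ab_network):
        # at [A]=[B]=1 with reference (2/3, 4/3):
        # 2 ln2 + 1 ln(1/2) = ln2 (in units of R)
        ref = np.array([2.0 / 3.0, 4.0 / 3.0])
        s = nf.entropy_production_relative(ab_network,
                                           np.array([1.0, 1.0]), ref)
        assert s == pytest.approx(R_GAS * np.log(2.0), rel=1e-12)

    def test_zero_at_reference_itself(self, ab_network):
        ref = nf.reference_equilibrium(ab_network)
        assert nf.entropy_production_relative(ab_network, ref, ref) == \
            pytest.approx(0.0, abs=1e-14)

    def test_identity_with_pairwise_form_on_consistent_networks(self):
        rng = np.random.default_rng(17)
        for seed in range(10):
            net = nf.random_network(4, 4, driven=False, seed=seed)
            for _ in range(10):
                c = np.exp(rng.uniform(np.log(0.05), np.log(2.0),
                                       net.n_species))
                ref = nf.reference_equilibrium(net, c)
                s11 = nf.entropy_production_internal(net, c)
                s14 = nf.entropy_production_relative(net, c, ref)
                assert abs(s14 - s11) / max(s11, R_GAS) < 1e-10

    def test_non_equilibrium_reference_rejected(self, ab_network):
        with pytest.raises(DomainError):
            nf.entropy_production_relative(ab_network, np.array([1.0, 1.0]),
                                           np.array([1.0, 1.0]))

    def test_wegscheider_violation_detected(self):
        # triangle A->B->C->A with inconsistent constants
        text = (
            "species A init=1.0\nspecies B init=1.0\nspecies C init=1.0\n"
            "reaction R1: A <-> B ; kf=2.0, kr=1.0\n"
            "reaction R2: B <-> C ; kf=2.0, kr=1.0\n"
            "reaction R3: C <-> A ; kf=2.0, kr=1.0\n")
        net = nf.parse_network(text)
        with pytest.raises(WegscheiderError):
            nf.reference_equilibrium(net)


class TestExchangeAndBalance:
    def test_closed_network_exchanges_nothing(self, ab_network):
        assert nf.entropy_exchange(ab_network, np.array([0.5, 0.5])) == 0.0

    def test_balance_exact_at_competitive_ness(self, competitive_network,
                                               competitive_ness):
        bal = nf.balance_residual(competitive_network, competitive_ness.conc)
        assert bal.sigma_int > 0
        assert abs(bal.sigma_total) < 1e-10 * max(bal.sigma_int, R_GAS)
        assert bal.is_stationary
        assert not bal.clamped

    def test_balance_exact_at_frank_states(self, frank_network, frank_states):
        ref = nf.reference_equilibrium(frank_network, frank_states[0].conc)
        for s in frank_states:
            bal = nf.balance_residual(frank_network, s.conc, ref=ref)
            assert abs(bal.sigma_total) < 1e-10 * max(bal.sigma_int, R_GAS)

    def test_clamped_network_is_labeled(self, schlogl_network):
        states = nf.find_steady_states(schlogl_network, n_starts=32, seed=3)
        bal = nf.balance_residual(schlogl_network, states[0].conc)
        assert bal.clamped

    def test_off_ness_total_matches_free_energy_rate(self,
                                                     competitive_network):
        # sigma_int + sigma_exch = -(1/T) dG/dt with the same potentials
        net = competitive_network
        ref = nf.reference_equilibrium(net, np.array([1.0, 0.3, 0.05]))
        traj = nf.integrate(net, [1.0, 0.3, 0.05], 5.0,
                            t_eval=np.linspace(0.01, 5, 20))
        RT = net.gas_constant * net.temperature
        for c, dc in zip(traj.states, traj.derivatives):
            total = (nf.entropy_production_internal(net, c)
                     + nf.entropy_exchange(net, c, ref=ref))
            dGdt = float(np.sum(RT * np.log(c / ref) * dc))
            assert abs(total + dGdt / net.temperature) <= \
                1e-8 * max(abs(total), R_GAS)

    def test_balance_only_points_flagged(self, competitive_network,
                                         competitive_ness):
        # the zero-balance set is a curve: almost all of its points are
        # non-stationary and must be reported as balance-only
        net = competitive_network
        c_star = competitive_ness.conc
        res = nf.balance_zero_contour(
            net, ("C", "D"), np.linspace(0.3, 2.0, 7) * c_star[1],
            np.linspace(0.3, 2.0, 7) * c_star[2], base=c_star)
        ref = nf.reference_equilibrium(net, c_star)
        off = np.nonzero(~res.is_stationary)[0]
        assert len(off) >= 3
        for i in off[:3]:
            c = c_star.copy()
            c[1], c[2] = res.points[i]
            bal = nf.balance_residual(net, c, ref=ref)
            assert bal.balance_only and not bal.is_stationary


class TestGEC:
    def test_force_part_never_positive(self):
        nets = [nf.make_ab(), nf.make_competitive(), nf.make_frank(),
                nf.make_schlogl()]
        starts = [[0.9, 0.1], [1.0, 0.3, 0.05],
                  [1.0, 0.02, 0.01, 0.005], [1.0, 0.5, 1.0]]
        for net, c0 in zip(nets, starts):
            traj = nf.integrate(net, c0, 30.0,
                                t_eval=np.linspace(0.01, 30, 60))
            for rec in nf.gec_decomposition(net, traj):
                assert rec.dFP <= 1e-10 * max(abs(rec.dFP), R_GAS)

    def test_closed_form_of_force_part(self, competitive_network):
        # dFP = -R sum dc^2/c, via an algebraically independent expression
        traj = nf.integrate(competitive_network, [1.0, 0.3, 0.05], 10.0,
                            t_eval=np.linspace(0.05, 10, 30))
        recs = nf.gec_decomposition(competitive_network, traj)
        for rec, c in zip(recs, traj.states):
            cf = nf.gec_force_closed_form(competitive_network, c)
            assert abs(rec.dFP - cf) <= 1e-10 * max(abs(cf), R_GAS)

    def test_analytic_derivatives_match_finite_differences(self, ab_network):
        # directional FD along the flow: c(t +/- h) ~ c +/- h*dc/dt
        net = ab_network
        c = np.array([0.8, 0.2])
        dc = net.time_derivatives(c)
        h = 1e-7

        def P_of(cc):
            return gec_point(net, cc)[0]

        dP_fd = (P_of(c + h * dc) - P_of(c - h * dc)) / (2 * h)
        P, dP, dFP, dJP, _ = gec_point(net, c)
        assert dP == pytest.approx(dP_fd, rel=1e-7)
        assert dP == pytest.approx(dFP + dJP, rel=1e-12)

    def test_near_equilibrium_force_and_current_parts_agree(self, ab_network):
        # linear regime: dFP ~ dJP and sigma_int decreases monotonically
        ceq = nf.reference_equilibrium(ab_network, np.array([1.0, 0.0]))
        c0 = ceq * (1 + np.array([1e-4, -5e-5]))
        Af = nf.affinities(ab_network, c0)
        assert np.max(np.abs(Af)) / RT300 < 1e-3
        traj = nf.integrate(ab_network, c0, 5.0,
                            t_eval=np.linspace(0, 5, 40))
        recs = nf.gec_decomposition(ab_network, traj)
        for rec in recs:
            if abs(rec.dFP) > 1e-25:
                assert abs(rec.dFP - rec.dJP) / abs(rec.dFP) < 1e-2
        sig = [r.sigma_int for r in recs]
        assert np.all(np.diff(sig) <= 1e-12 * max(sig))

    def test_nonpositive_concentration_rejected_with_time(self, ab_network):
        traj = nf.integrate(ab_network, [1.0, 0.0], 1.0,
                            t_eval=np.array([0.0, 1.0]))
        with pytest.raises(DomainError, match="t = "):
            nf.gec_decomposition(ab_network, traj)


class TestLocalPotentialProbe:
    def test_stable_competitive_ness_is_a_well(self, competitive_network,
                                               competitive_ness):
        rep = nf.local_potential_probe(competitive_network, competitive_ness,
                                       n_directions=8, seed=2)
        assert rep.classification == "well"
        assert rep.all_returned
        assert rep.gec_ok

    def test_frank_racemic_saddle_structure(self, frank_network,
                                            frank_states):
        net = frank_network
        rac = next(s for s in frank_states
                   if abs(nf.enantiomeric_excess(net, s.conc)) < 1e-8)
        others = [s.conc for s in frank_states if s is not rac]
        iL, iD = net.species_index("L"), net.species_index("D")
        sym = np.zeros(net.n_species)
        anti = np.zeros(net.n_species)
        sym[iL] = sym[iD] = 1.0
        anti[iL], anti[iD] = 1.0, -1.0
        rep = nf.local_potential_probe(
            net, rac, n_directions=8, seed=2,
            named_directions={"sym": sym, "anti": anti},
            known_attractors=others)
        assert rep.classification == "saddle"
        fates = {f.name: f.fate for f in rep.fates}
        assert fates["sym"] == "returned"
        assert fates["anti"].startswith("escaped:attractor")
        assert rep.gec_ok

    def test_closed_equilibrium_is_a_well(self, ab_network):
        states = nf.find_steady_states(ab_network, n_starts=8, seed=4)
        rep = nf.local_potential_probe(ab_network, states[0],
                                       n_directions=8, seed=4)
        assert rep.classification == "well"


class TestZeroBalanceContour:
    def test_contour_is_a_curve_containing_one_ness(self, competitive_network,
                                                    competitive_ness):
        c_star = competitive_ness.conc
        net = competitive_network
        # grids pass exactly through the NESS values of C and D
        g1 = np.unique(np.append(np.linspace(0.2, 2.0, 7) * c_star[1],
                                 c_star[1]))
        g2 = np.unique(np.append(np.linspace(0.2, 2.0, 7) * c_star[2],
                                 c_star[2]))
        res = nf.balance_zero_contour(net, ("C", "D"), g1, g2, base=c_star)
        assert len(res.points) > 3            # a curve, not one point
        assert res.is_stationary.sum() >= 1   # containing the NESS
        assert (~res.is_stationary).sum() >= 3

    def test_balance_changes_sign_across_contour(self, competitive_network,
                                                 competitive_ness):
        net = competitive_network
        c_star = competitive_ness.conc
        ref = nf.reference_equilibrium(net, c_star)
        res = nf.balance_zero_contour(
            net, ("C", "D"), np.linspace(0.3, 2.0, 6) * c_star[1],
            np.linspace(0.3, 2.0, 6) * c_star[2], base=c_star)

        def total(x, y):
            c = c_star.copy()
            c[1], c[2] = x, y
            return (nf.entropy_production_internal(net, c)
                    + nf.entropy_exchange(net, c, ref=ref))

        x, y = res.points[0]
        eps = 1e-4 * y
        assert total(x, y - eps) * total(x, y + eps) < 0 or \
            total(x - 1e-4 * x, y) * total(x + 1e-4 * x, y) < 0

    def test_closed_network_rejected(self, ab_network):
        with pytest.raises(DomainError):
            nf.balance_zero_contour(ab_network, ("A", "B"),
                                    np.linspace(0.1, 1, 4),
                                    np.linspace(0.1, 1, 4))


class TestSelectivityIdentity:
    def test_residual_vanishes_at_default_ness(self, competitive_network,
                                               competitive_ness):
        rep = nf.selectivity_identity_residual(
            competitive_network, competitive_ness.conc, "RC", "RD")
        assert rep.ratio == pytest.approx(5.5, rel=1e-8)
        assert rep.residual < 1e-10

    def test_low_flow_limit_is_equilibrium_selectivity(self):
        net = nf.make_competitive(flow=1e-5)
        traj = nf.integrate_to_steady(net, net.init_conc, steady_tol=1e-12,
                                      t_max=1e9)
        c = traj.final_state
        # KeqC/KeqD = 1: selectivity -> 1 as f -> 0
        assert c[1] / c[2] == pytest.approx(1.0, abs=1e-3)

    def test_enantiomer_selectivity_is_unity(self):
        net = nf.make_enantiomeric()
        traj = nf.integrate_to_steady(net, [1.0, 0.3, 0.0],
                                      steady_tol=1e-12)
        c = traj.final_state
        assert c[1] / c[2] == pytest.approx(1.0, abs=1e-8)
        rep = nf.selectivity_identity_residual(net, c, "RC", "RD")
        assert rep.residual < 1e-10
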