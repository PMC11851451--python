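"""Shared-ligand speciation solver, oligo masses, spectrum prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groovebind import (
    DnaSpeciesSpec,
    LigandSpec,
    StepwiseConstants,
    oligo_average_mass,
    predict_ms_spectrum,
    solve_free_ligand,
    species_distribution,
)

K_strat = st.floats(min_value=1e4, max_value=1e9)
total_strat = st.floats(min_value=1e-7, max_value=1e-4)


def fig2_mixture():
    """The published competition design: 10 uM each DNA + 20 uM DB1003."""
    return (
        [
            DnaSpeciesSpec("TTAA", 10e-6, StepwiseConstants.two_site(2.6e6, 7.5e7), mass=5604.7),
            DnaSpeciesSpec("AATT", 10e-6, StepwiseConstants.one_site(2e6), mass=6132.0),
        ],
        LigandSpec("DB1003", 20e-6, mass=344.4),
    )


class TestSolveFreeLigand:
    def test_zero_ligand(self):
        mixture, _ = fig2_mixture()
        assert solve_free_ligand(mixture, LigandSpec("x", 0.0)) == 0.0

    def test_no_dna_returns_total(self):
        assert solve_free_ligand([], LigandSpec("x", 2e-5)) == 2e-5

    def test_against_dense_grid_search(self):
        """Root agrees with a 1e6-point brute-force scan of the balance."""
        mixture, ligand = fig2_mixture()
        L = solve_free_ligand(mixture, ligand)
        grid = np.linspace(0.0, ligand.total, 1_000_001)
        balance = grid + sum(
            spec.total * np.asarray(spec.binding.fraction_bound(grid)) for spec in mixture
        )
        L_grid = grid[np.argmin(np.abs(balance - ligand.total))]
        assert abs(L - L_grid) <= ligand.total / 1_000_000

    def test_against_independent_full_system_solve(self, rng):
        """Matches a bounded solve of the complete speciation equations."""
        for _ in range(25):
            mixture, ligand = random_mixture(rng)
            L = solve_free_ligand(mixture, ligand)
            L_ref = full_system_free_ligand(mixture, ligand)
            assert L == pytest.approx(L_ref, rel=1e-8)

    @given(
        K1=K_strat,
        K2=K_strat,
        K_mono=K_strat,
        D1=total_strat,
        D2=total_strat,
        Ltot=total_strat,
    )
    @settings(max_examples=60, deadline=None)
    def test_mass_balance_closes(self, K1, K2, K_mono, D1, D2, Ltot):
        mixture = [
            DnaSpeciesSpec("a", D1, StepwiseConstants.two_site(K1, K2)),
            DnaSpeciesSpec("b", D2, StepwiseConstants.one_site(K_mono)),
        ]
        dist = species_distribution(mixture, LigandSpec("lig", Ltot))
        for err in dist.mass_balance_errors().values():
            assert err < 1e-9

    def test_bound_ligand_monotone_in_total_ligand(self):
        """More total ligand never lowers any DNA's bound-ligand load.

        (The 1:1 intermediate of a two-site DNA legitimately shrinks as
        it converts to the 2:1 complex, so the monotone quantity is the
        bound ligand per DNA, not each individual complex.)
        """
        mixture, _ = fig2_mixture()
        totals = np.linspace(1e-6, 5e-5, 25)
        prev_bound, prev_free = None, None
        for Ltot in totals:
            dist = species_distribution(mixture, LigandSpec("lig", Ltot))
            bound = np.array([s.bound_ligand for s in dist.per_dna.values()])
            if prev_bound is not None:
                assert np.all(bound >= prev_bound - 1e-15)
                assert dist.free_ligand >= prev_free - 1e-15
            prev_bound, prev_free = bound, dist.free_ligand


def random_mixture(rng, max_species: int = 3):
    """Random competition mixture: K in [1e4, 1e9] M^-1, totals in [1e-7, 1e-4] M."""
    n = rng.integers(1, max_species + 1)
    mixture = []
    for j in range(n):
        if rng.random() < 0.5:
            binding = StepwiseConstants.one_site(10 ** rng.uniform(4, 9))
        else:
            binding = StepwiseConstants.two_site(
                10 ** rng.uniform(4, 9), 10 ** rng.uniform(4, 9)
            )
        mixture.append(DnaSpeciesSpec(f"d{j}", 10 ** rng.uniform(-7, -4), binding))
    return mixture, LigandSpec("lig", 10 ** rng.uniform(-7, -4))


def full_system_free_ligand(mixture, ligand) -> float:
    """Independent oracle: bounded least-squares on the full speciation system.

    Unknowns are (L/Ltot, D_j/Dtot_j) in [0, 1]; residuals are the
    relative ligand- and DNA-balance violations.
    """
    from scipy.optimize import least_squares

    def bound_per_free_dna(b, L_):
        if b.K_A is not None:
            return b.K_A * L_
        return b.K_A1 * L_ + 2.0 * b.K_A1 * b.K_A2 * L_**2

    def resid(x):
        L_ = x[0] * ligand.total
        D = [xi * s.total for xi, s in zip(x[1:], mixture)]
        eqs = [
            (
                L_
                + sum(Dj * bound_per_free_dna(s.binding, L_) for Dj, s in zip(D, mixture))
                - ligand.total
            )
            / ligand.total
        ]
        for Dj, s in zip(D, mixture):
            eqs.append((Dj * float(s.binding.binding_polynomial(L_)) - s.total) / s.total)
        return eqs

    x0 = np.full(1 + len(mixture), 0.5)
    sol = least_squares(resid, x0, bounds=(0, 1), xtol=3e-16, ftol=3e-16, gtol=3e-16)
    if np.max(np.abs(sol.fun)) > 1e-10:
        raise RuntimeError("oracle solve did not converge")
    return float(sol.x[0] * ligand.total)


class TestSpeciesDistribution:
    def test_saturating_ligand_drives_highest_stoichiometry(self):
        mixture = [
            DnaSpeciesSpec("dimer", 1e-6, StepwiseConstants.two_site(1e8, 1e9)),
            DnaSpeciesSpec("mono", 1e-6, StepwiseConstants.one_site(1e9)),
        ]
        dist = species_distribution(mixture, LigandSpec("lig", 1e-3))
        assert dist.per_dna["dimer"].complex_2to1 / 1e-6 > 0.99
        assert dist.per_dna["mono"].complex_1to1 / 1e-6 > 0.99

    def test_competition_favors_the_cooperative_dimer_site(self):
        """The -TTAA- 2:1 fraction exceeds any -AATT- complex fraction."""
        mixture, ligand = fig2_mixture()
        dist = species_distribution(mixture, ligand)
        ttaa = dist.per_dna["TTAA"]
        aatt = dist.per_dna["AATT"]
        frac_ttaa_dimer = ttaa.complex_2to1 / 10e-6
        frac_aatt_complexed = (aatt.complex_1to1 + aatt.complex_2to1) / 10e-6
        assert frac_ttaa_dimer > frac_aatt_complexed

    def test_vanishing_affinity_leaves_everything_free(self):
        mixture = [DnaSpeciesSpec("d", 1e-5, StepwiseConstants.one_site(1e-6))]
        ligand = LigandSpec("lig", 2e-5)
        dist = species_distribution(mixture, ligand)
        assert dist.free_ligand == pytest.approx(2e-5, rel=1e-6)
        assert dist.per_dna["d"].free == pytest.approx(1e-5, rel=1e-6)


class TestOligoMass:
    # reference values computed once with an independent oligonucleotide
    # mass calculator (average masses, 5'-monophosphate / 5'-OH conventions)
    FROZEN = {
        ("A", "phosphate"): 331.2218,
        ("A", "OH"): 251.2419,
        ("ACGT", "phosphate"): 1253.8027,
        ("GCGAATTCGC", "phosphate"): 3107.9778,
    }

    @pytest.mark.parametrize("key", sorted(FROZEN))
    def test_against_frozen_reference(self, key):
        seq, five_prime = key
        assert oligo_average_mass(seq, five_prime) == pytest.approx(self.FROZEN[key], abs=0.1)

    def test_composition_invariance(self):
        assert oligo_average_mass("ACGT") == pytest.approx(oligo_average_mass("TGCA"), abs=1e-9)

    @pytest.mark.parametrize("bad", ["", "ACGX", "AC GT"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            oligo_average_mass(bad)


class TestSpectrumPrediction:
    def test_single_species_peak_is_100(self):
        mixture = [DnaSpeciesSpec("d", 1e-5, StepwiseConstants.one_site(1e-6), mass=6000.0)]
        dist = species_distribution(mixture, LigandSpec("lig", 0.0, mass=350.0))
        peaks = predict_ms_spectrum(dist, populated_threshold=1e-6)
        assert len(peaks) == 1
        assert peaks[0].intensity == 100.0
        assert peaks[0].mass == 6000.0

    def test_mass_additivity_along_the_complex_ladder(self):
        mixture = [DnaSpeciesSpec("d", 1e-5, StepwiseConstants.two_site(1e7, 1e7), mass=6000.0)]
        dist = species_distribution(mixture, LigandSpec("lig", 2e-5, mass=350.0))
        peaks = {p.species: p for p in predict_ms_spectrum(dist, populated_threshold=1e-9)}
        assert peaks["d+2lig"].mass - peaks["d+1lig"].mass == pytest.approx(350.0, abs=1e-9)
        assert peaks["d+1lig"].mass - peaks["d"].mass == pytest.approx(350.0, abs=1e-9)

    def test_published_competition_scenario_tallest_ttaa_peak_is_dimer(self):
        mixture, ligand = fig2_mixture()
        dist = species_distribution(mixture, ligand)
        peaks = predict_ms_spectrum(dist, populated_threshold=1e-9)
        ttaa = [p for p in peaks if p.species.startswith("TTAA")]
        tallest = max(ttaa, key=lambda p: p.intensity)
        assert tallest.species == "TTAA+2DB1003"

    def test_missing_mass_for_populated_species_raises(self):
        mixture = [DnaSpeciesSpec("d", 1e-5, StepwiseConstants.one_site(1e6), mass=6000.0)]
        dist = species_distribution(mixture, LigandSpec("lig", 1e-5, mass=None))
        with pytest.raises(ValueError, match="no mass"):
            predict_ms_spectrum(dist)
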