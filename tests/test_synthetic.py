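"""Synthetic specimens and cohorts: distributions, determinism, protocol
annotations, and the cohort's clustered structure."""

import numpy as np
import pytest

from poroindent.material import FRPEParameters
from poroindent.synthetic import (
    CohortSpec,
    GroupParameterModel,
    NoiseModel,
    draw_parameters,
    experiment_from_simulation,
    generate_cohort,
)


class TestDrawParameters:
    def test_degenerate_scale_returns_group_median(self):
        model = GroupParameterModel(
            log_scales={g: {k: 0.0 for k in FRPEParameters.names()}
                        for g in ("normal", "moderate", "severe")}
        )
        p = draw_parameters("normal", model, np.random.default_rng(0))
        med = model.medians["normal"]
        for name in FRPEParameters.names():
            assert getattr(p, name) == pytest.approx(med[name])

    def test_seeded_determinism(self):
        model = GroupParameterModel()
        a = draw_parameters("severe", model, np.random.default_rng(42))
        b = draw_parameters("severe", model, np.random.default_rng(42))
        assert a == b

    def test_group_medians_preserve_oa_contrast(self):
        """Monte-Carlo check of the configured distributions: severe OA
        draws have higher permeability and lower initial fibril modulus."""
        model = GroupParameterModel()
        rng = np.random.default_rng(7)
        draws = {g: [draw_parameters(g, model, rng) for _ in range(4000)]
                 for g in ("normal", "severe")}
        med = {g: {n: np.median([getattr(p, n) for p in ps])
                   for n in ("Ef0", "k0")} for g, ps in draws.items()}
        assert med["severe"]["k0"] > med["normal"]["k0"]
        assert med["severe"]["Ef0"] < med["normal"]["Ef0"]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            draw_parameters("mild", GroupParameterModel(), np.random.default_rng(0))


class TestGenerateExperiment:
    def test_zero_noise_record_equals_resampled_simulation(self, paper_sim, geometry):
        exp = experiment_from_simulation(paper_sim, geometry,
                                         NoiseModel(force_noise=0.0),
                                         np.random.default_rng(0))
        expect = np.interp(exp.time, paper_sim.time, paper_sim.force)
        assert np.array_equal(exp.force, expect)

    def test_annotations_match_protocol(self, full_experiment):
        assert len(full_experiment.steps) == 4
        assert len(full_experiment.dynamic) == 8
        freqs = [b.frequency for b in full_experiment.dynamic]
        assert freqs == sorted(freqs)
        for i, s in enumerate(full_experiment.steps):
            assert s.strain_end - s.strain_start == pytest.approx(0.05)

    def test_equilibrium_modulus_invariant_under_resampling(self, paper_sim,
                                                            geometry, full_experiment):
        """E_eq from the resampled record matches the value computed on the
        raw simulation grid."""
        from poroindent.analysis import equilibrium_modulus

        raw = experiment_from_simulation(paper_sim, geometry,
                                         NoiseModel(force_noise=0.0,
                                                    relaxation_rate=50.0),
                                         np.random.default_rng(0))
        e1 = equilibrium_modulus(full_experiment).E_eq
        e2 = equilibrium_modulus(raw).E_eq
        assert e1 == pytest.approx(e2, rel=0.01)

    def test_noise_is_seeded(self, paper_sim, geometry):
        a = experiment_from_simulation(paper_sim, geometry, NoiseModel(0.01),
                                       np.random.default_rng(5))
        b = experiment_from_simulation(paper_sim, geometry, NoiseModel(0.01),
                                       np.random.default_rng(5))
        assert np.array_equal(a.force, b.force)
        c = experiment_from_simulation(paper_sim, geometry, NoiseModel(0.01),
                                       np.random.default_rng(6))
        assert not np.array_equal(a.force, c.force)


class TestGenerateCohort:
    def test_default_cohort_mirrors_study_sizes(self):
        cohort = generate_cohort(CohortSpec(), np.random.default_rng(0))
        assert len(cohort) == 35
        assert cohort.group_sizes() == {"normal": 17, "moderate": 15, "severe": 3}

    def test_single_sample_spec(self):
        cohort = generate_cohort(CohortSpec(n_normal=0, n_moderate=0, n_severe=1),
                                 np.random.default_rng(0))
        assert len(cohort) == 1 and cohort.samples[0].group == "severe"

    def test_bit_reproducible(self):
        a = generate_cohort(CohortSpec(), np.random.default_rng(11)).to_frame()
        b = generate_cohort(CohortSpec(), np.random.default_rng(11)).to_frame()
        assert a.equals(b)

    def test_two_sample_knees_hold_both_compartments(self):
        df = generate_cohort(CohortSpec(), np.random.default_rng(2)).to_frame()
        paired = df.groupby("knee_id").filter(lambda g: len(g) == 2)
        assert len(paired) > 0
        for _, g in paired.groupby("knee_id"):
            assert set(g.compartment) == {"medial", "lateral"}

    def test_within_knee_correlation_raises_icc(self):
        """Ground-truth Enf similarity within two-sample knees must grow
        with the configured knee correlation."""

        def icc(rho, seed):
            spec = CohortSpec(model=GroupParameterModel(knee_correlation=rho),
                              n_normal=35, n_moderate=0, n_severe=0,
                              paired_fraction=1.0)
            vals = []
            for s in range(seed, seed + 30):
                df = generate_cohort(spec, np.random.default_rng(s)).to_frame()
                pairs = (df.groupby("knee_id")["Enf"]
                         .apply(lambda v: tuple(np.log(v))).tolist())
                pairs = [p for p in pairs if len(p) == 2]
                a = np.array(pairs)
                vals.append(np.corrcoef(a[:, 0], a[:, 1])[0, 1])
            return np.mean(vals)

        assert icc(0.9, 100) > icc(0.0, 100) + 0.3

    def test_grades_consistent_with_groups(self):
        df = generate_cohort(CohortSpec(), np.random.default_rng(3)).to_frame()
        assert set(df[df.group == "normal"].oarsi_grade) <= {0, 1}
        assert set(df[df.group == "moderate"].oarsi_grade) <= {2, 3}
        assert set(df[df.group == "severe"].oarsi_grade) == {4}
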