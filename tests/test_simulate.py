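"""Synthetic generator: determinism, schema validity, truth recovery."""

import numpy as np
import pytest

from brainpk import io as bio
from brainpk.binding import DialysisRecord, SliceAssayRecord, compute_fu_plasma, compute_vu_brain
from brainpk.distribution import ConcentrationRecord, Genotype, analyze_animal
from brainpk.exceptions import InvalidInputError, QCFailureError
from brainpk.simulate import (
    NoiseModel,
    default_truth,
    generate_all,
    generate_cohort,
    generate_dialysis,
    generate_slices,
    generate_srm,
)


def _analyze_group(df, truth, drug, genotype):
    g = truth.drugs[(drug, genotype)]
    sub = df[(df.drug == drug) & (df.genotype == genotype)]
    kpuus = []
    for r in sub.itertuples():
        rec = ConcentrationRecord(
            r.animal_id, Genotype(genotype), drug,
            r.c_plasma_ng_ml, r.c_brain_homog_ng_ml, r.homogenate_dilution,
        )
        kpuus.append(
            analyze_animal(rec, g.v_u_brain, g.f_u_plasma, truth.vascular).kpuu
        )
    return float(np.mean(kpuus))


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        truth = default_truth(seed=123)
        p1 = generate_all(truth, tmp_path / "a")
        p2 = generate_all(truth, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name

    def test_different_seeds_differ(self):
        a = generate_cohort(default_truth(seed=1))
        b = generate_cohort(default_truth(seed=2))
        assert not a["c_plasma_ng_ml"].equals(b["c_plasma_ng_ml"])

    def test_streams_are_independent(self):
        """Cohort output is unaffected by whether other tables are generated."""
        truth = default_truth(seed=5)
        first = generate_cohort(truth)
        generate_srm(truth)
        generate_dialysis(truth)
        again = generate_cohort(truth)
        assert first.equals(again)


class TestSchemaValidity:
    def test_generated_files_validate_cleanly(self, tmp_path, zero_noise_truth):
        paths = generate_all(zero_noise_truth, tmp_path)
        kinds = {
            "concentrations.csv": "concentrations",
            "dialysis.csv": "dialysis",
            "slices.csv": "slices",
            "srm_transitions.csv": "srm_transitions",
        }
        for name, kind in kinds.items():
            assert bio.validate_table(paths[name], kind) == []


class TestZeroNoiseRecovery:
    def test_kpuu_inversion(self, zero_noise_truth):
        df = generate_cohort(zero_noise_truth, n_per_group=3)
        for (drug, genotype), g in zero_noise_truth.drugs.items():
            got = _analyze_group(df, zero_noise_truth, drug, genotype)
            assert got == pytest.approx(g.kpuu, rel=1e-10), (drug, genotype)

    def test_verapamil_humanized_kpuu_value(self, zero_noise_truth):
        got = _analyze_group(
            generate_cohort(zero_noise_truth, 3), zero_noise_truth, "verapamil", "HMDR1"
        )
        assert round(got, 2) == 1.60

    def test_fu_inversion(self, zero_noise_truth):
        df = generate_dialysis(zero_noise_truth, replicates=3)
        sub = df[(df.drug == "oxycodone") & (df.genotype == "C57BL6_WT")]
        recs = [
            DialysisRecord("oxycodone", r.replicate_id, r.c_buffer_side_ng_ml, r.c_plasma_side_ng_ml)
            for r in sub.itertuples()
        ]
        assert compute_fu_plasma(recs).fu_mean == pytest.approx(0.681, rel=1e-10)

    def test_vu_inversion(self, zero_noise_truth):
        df = generate_slices(zero_noise_truth, n_slices=6)
        sub = df[df.drug == "digoxin"]
        recs = [
            SliceAssayRecord(
                "digoxin", r.slice_id, r.slice_weight_g, r.c_buffer_final_ng_ml,
                r.c_slice_homog_ng_ml, r.slice_dilution, r.end_ph, r.ldh_release_fraction,
            )
            for r in sub.itertuples()
        ]
        assert compute_vu_brain(recs).vu_mean == pytest.approx(44.8, rel=1e-10)


class TestSliceFailures:
    def _records(self, df, drug="digoxin"):
        return [
            SliceAssayRecord(
                drug, r.slice_id, r.slice_weight_g, r.c_buffer_final_ng_ml,
                r.c_slice_homog_ng_ml, r.slice_dilution, r.end_ph, r.ldh_release_fraction,
            )
            for r in df[df.drug == drug].itertuples()
        ]

    def test_all_failing_raises(self, zero_noise_truth):
        df = generate_slices(zero_noise_truth, n_slices=6, fail_fraction=1.0)
        with pytest.raises(QCFailureError):
            compute_vu_brain(self._records(df))

    def test_poisoned_failures_leave_mean_unchanged(self, zero_noise_truth):
        clean = generate_slices(zero_noise_truth, n_slices=6, fail_fraction=0.0)
        mixed = generate_slices(zero_noise_truth, n_slices=6, fail_fraction=0.5)
        vu_clean = compute_vu_brain(self._records(clean)).vu_mean
        res = compute_vu_brain(self._records(mixed))
        assert res.vu_mean == pytest.approx(vu_clean, rel=1e-12)
        assert res.n_fail == 3

    def test_fail_fraction_range_checked(self, zero_noise_truth):
        with pytest.raises(InvalidInputError):
            generate_slices(zero_noise_truth, fail_fraction=1.5)


class TestNoisyRecovery:
    def test_kpuu_median_bias_small(self):
        """CV=10%, n=5, 200 seeded replicates: median |bias| of Kp,uu < 5%."""
        errs = []
        for rep in range(200):
            truth = default_truth(
                seed=20_000 + rep, noise=NoiseModel(0.10, 0.0, 0.0, 0.0)
            )
            df = generate_cohort(truth, n_per_group=5)
            g = truth.drugs[("verapamil", "HMDR1")]
            got = _analyze_group(df, truth, "verapamil", "HMDR1")
            errs.append(abs(got - g.kpuu) / g.kpuu)
        assert float(np.median(errs)) < 0.05
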