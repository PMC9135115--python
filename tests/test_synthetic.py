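"""Synthetic benchmark data: planted exactness, background shape, determinism."""

import itertools
import json
from fractions import Fraction

import pytest

from feasquery.executor import count_query
from feasquery.store import ResourceStore
from feasquery.synthetic import (
    BackgroundSpec,
    ScaleError,
    benchmark_queries,
    expected_counts,
    generate,
    get_profile,
    iter_background,
    iter_dataset,
    plan_cohorts,
    terminology_for,
    write_dataset,
)


class TestProfiles:
    @pytest.mark.parametrize(
        "name, patients, conditions, procedures, observations, total",
        [
            ("small", 111_000, 111_000, 111_000, 111_000, 444_000),
            ("bg-small", 111_000, 524_375, 381_505, 5_018_600, 6_035_480),
            ("bg-large", 1_111_000, 1_524_375, 1_381_505, 6_018_600, 10_035_480),
        ],
    )
    def test_builtin_profiles_imply_the_documented_counts(
        self, name, patients, conditions, procedures, observations, total
    ):
        counts = expected_counts(get_profile(name))
        assert counts["Patient"] == patients
        assert counts["Condition"] == conditions
        assert counts["Procedure"] == procedures
        assert counts["Observation"] == observations
        assert counts["total"] == total

    def test_unknown_profile(self):
        with pytest.raises(KeyError, match="unknown profile"):
            get_profile("huge")

    def test_non_integer_scale_names_the_count(self):
        with pytest.raises(ScaleError, match="cohort size 1000"):
            plan_cohorts(get_profile("small", "1/3"))

    def test_scale_must_be_positive(self):
        with pytest.raises(ScaleError):
            get_profile("small", "-1")


class TestCohortPlanning:
    def test_genders_distinct_and_female_on_100k(self):
        cohorts = plan_cohorts(get_profile("bg-large", "1/1000"))
        genders = [c.gender for c in cohorts]
        assert len(set(genders)) == len(genders)
        assert next(c for c in cohorts if c.label == "100000").gender == "female"

    def test_example_codes_on_the_100k_cohort(self):
        cohort = next(c for c in plan_cohorts(get_profile("small"))
                      if c.label == "100000")
        assert cohort.condition_code.code == "C50.1"
        assert cohort.procedure_code.code == "5-787.ex"
        assert cohort.observation_code.code == "55782-7"

    def test_cohort_codes_unique_across_cohorts(self):
        cohorts = plan_cohorts(get_profile("bg-large", "1/1000"))
        codes = [c.condition_code for c in cohorts] + [c.procedure_code for c in cohorts] \
            + [c.observation_code for c in cohorts]
        assert len(set(codes)) == len(codes)


SCALE = Fraction(1, 1000)


@pytest.fixture(scope="module")
def small_scaled():
    profile = get_profile("small", SCALE)
    return profile, generate(profile, seed=42)


class TestGeneration:
    SCALE = SCALE

    def test_scaled_counts(self, small_scaled):
        _, store = small_scaled
        assert store.counts_by_type() == {
            "Patient": 111, "Condition": 111, "Procedure": 111, "Observation": 111}

    def test_every_planted_query_is_exact_at_scale(self, small_scaled):
        profile, store = small_scaled
        tree, mapping = terminology_for(profile)
        for label, q in benchmark_queries(profile):
            result = count_query(q, store, tree, mapping)
            if label == "0":
                assert (result.patient_count, result.resources_processed) == (0, 0)
            else:
                size = int(label.split("-")[0]) // 1000
                assert result.patient_count == size
                expected_resources = size if label.endswith("-1") else 4 * size
                assert result.resources_processed == expected_resources

    def test_benchmark_suite_shape(self):
        profile = get_profile("small", self.SCALE)
        labels = [label for label, _ in benchmark_queries(profile)]
        assert labels == ["0", "1000-1", "1000-all", "10000-1", "10000-all",
                          "100000-1", "100000-all"]

    def test_determinism_byte_identical(self):
        profile = get_profile("small", self.SCALE)
        a = list(iter_dataset(profile, seed=7))
        b = list(iter_dataset(profile, seed=7))
        assert a == b
        c = list(iter_dataset(profile, seed=8))
        assert a != c

    def test_members_of_other_cohorts_never_match(self, small_scaled):
        """Planted codes are cohort-exclusive by construction."""
        profile, store = small_scaled
        cohorts = plan_cohorts(profile)
        tree, mapping = terminology_for(profile)
        boundaries = list(itertools.accumulate(c.size for c in cohorts))
        for i, cohort in enumerate(cohorts):
            lo = 0 if i == 0 else boundaries[i - 1]
            member_ids = {f"p{n}" for n in range(lo, boundaries[i])}
            for label, q in benchmark_queries(profile):
                if label == f"{cohort.label}-all":
                    result = count_query(q, store, tree, mapping)
                    assert set(result.patient_ids) == member_ids


class TestBackground:
    SPEC = BackgroundSpec(conditions=100, condition_codes=7, procedures=50,
                          procedure_codes=3, observations=200, observation_codes=9)

    def test_totals_and_balanced_code_distribution(self):
        per_code: dict[str, int] = {}
        for r in iter_background(self.SPEC, n_patients=11, seed=1, resource_type="Condition"):
            code = r["code"]["coding"][0]["code"]
            per_code[code] = per_code.get(code, 0) + 1
        assert sum(per_code.values()) == 100
        assert len(per_code) == 7
        assert max(per_code.values()) - min(per_code.values()) <= 1

    def test_round_robin_over_existing_patients(self):
        subjects = [r["subject"]["reference"]
                    for r in iter_background(self.SPEC, n_patients=11, seed=1,
                                             resource_type="Procedure")]
        assert subjects[:11] == [f"Patient/p{i}" for i in range(11)]
        assert subjects[11] == "Patient/p0"

    def test_background_codes_disjoint_from_cohort_codes(self):
        profile = get_profile("small", Fraction(1, 1000))
        cohort_codes = set()
        for c in plan_cohorts(profile):
            cohort_codes |= {c.condition_code.code, c.procedure_code.code,
                             c.observation_code.code}
        bg_codes = {r["code"]["coding"][0]["code"]
                    for r in iter_background(self.SPEC, n_patients=111, seed=1)}
        assert not (bg_codes & cohort_codes)

    def test_background_adds_no_patients_and_queries_stay_exact(self):
        """Background load must not disturb any planted answer."""
        profile = get_profile("small", Fraction(1, 1000))
        store = generate(profile, seed=3)
        resources = list(iter_dataset(profile, seed=3)) + list(
            iter_background(self.SPEC, n_patients=111, seed=3))
        noisy = ResourceStore.from_resources(resources)
        assert noisy.count("Patient") == store.count("Patient")
        tree, mapping = terminology_for(profile)
        for label, q in benchmark_queries(profile):
            assert (count_query(q, noisy, tree, mapping).patient_ids
                    == count_query(q, store, tree, mapping).patient_ids)


class TestWriteDataset:
    def test_manifest_and_files(self, tmp_path):
        profile = get_profile("small", Fraction(1, 1000))
        manifest = write_dataset(profile, seed=9, out_dir=tmp_path)
        assert manifest["counts"]["total"] == 444
        for name in ("Patient", "Condition", "Procedure", "Observation"):
            assert (tmp_path / f"{name}.ndjson").exists()
        assert json.loads((tmp_path / "manifest.json").read_text()) == manifest
        assert (tmp_path / "queries" / "1000-all.json").exists()

        # files reload into the same counts as direct generation
        store = ResourceStore()
        for path in sorted(tmp_path.glob("*.ndjson")):
            with path.open() as fh:
                store.extend(json.loads(line) for line in fh if line.strip())
        store.validate_references()
        assert store.counts_by_type() == generate(profile, seed=9).counts_by_type()

    def test_written_files_are_deterministic(self, tmp_path):
        profile = get_profile("small", Fraction(1, 1000))
        write_dataset(profile, seed=9, out_dir=tmp_path / "a")
        write_dataset(profile, seed=9, out_dir=tmp_path / "b")
        for name in ("Patient", "Condition", "Procedure", "Observation"):
            assert ((tmp_path / "a" / f"{name}.ndjson").read_bytes()
                    == (tmp_path / "b" / f"{name}.ndjson").read_bytes())
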