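import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from keyslice.curation import (
    LesionAnnotation,
    OrganLabels,
    build_training_set,
    expand_lesion_range,
    expansion_padding,
    generate_pseudo_findings,
    read_annotations_csv,
    read_organ_labels_csv,
    write_pairs_jsonl,
)
from keyslice.errors import ConfigError, InputError, MissingStudyError


def annotation(study="s1", key=10, area=None, bbox=None, sentence="a mass"):
    if bbox is None:
        side = int(np.ceil(np.sqrt(area)))
        bbox = (0, 0, side, int(np.ceil(area / side)))
    return LesionAnnotation(study_id=study, sentence=sentence, key_slice=key, bbox=bbox)


def brute_force_padding(area):
    if area > 6000:
        return 3
    if area > 4000:
        return 2
    if area > 2000:
        return 1
    return 0


class TestExpansionPadding:
    @pytest.mark.parametrize(
        "area,expected", [(1500, 0), (2500, 1), (4500, 2), (6500, 3)]
    )
    def test_published_thresholds(self, area, expected):
        assert expansion_padding(area) == expected

    @pytest.mark.parametrize("boundary,expected", [(2000, 0), (4000, 1), (6000, 2)])
    def test_exact_threshold_takes_smaller_padding(self, boundary, expected):
        # "larger than" is strict: exactly at a threshold stays below it
        assert expansion_padding(boundary) == expected

    def test_exhaustive_against_piecewise_lookup(self):
        for area in range(1, 10001):
            assert expansion_padding(area) == brute_force_padding(area)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InputError):
            expansion_padding(0)


class TestExpandLesionRange:
    def test_medium_lesion_pads_one_slice(self):
        ann = annotation(key=10, bbox=(0, 0, 50, 50))  # 2500 px
        assert expand_lesion_range(ann, n_slices=100) == [9, 10, 11]

    def test_large_lesion_clamped_at_volume_start(self):
        ann = annotation(key=1, bbox=(0, 0, 65, 100))  # 6500 px -> +-3
        assert expand_lesion_range(ann, n_slices=100) == [0, 1, 2, 3, 4]

    def test_small_lesion_single_slice_volume(self):
        ann = annotation(key=0, bbox=(0, 0, 25, 40))  # 1000 px -> +-0
        assert expand_lesion_range(ann, n_slices=1) == [0]

    def test_key_slice_out_of_range(self):
        with pytest.raises(InputError):
            expand_lesion_range(annotation(key=5, bbox=(0, 0, 2, 2)), n_slices=3)

    @given(
        key=st.integers(0, 49),
        area=st.integers(1, 9000),
        n=st.integers(1, 50),
    )
    def test_slice_links_match_brute_force_enumeration(self, key, area, n):
        if key >= n:
            return
        ann = annotation(key=key, area=area)
        got = expand_lesion_range(ann, n_slices=n)
        p = brute_force_padding(ann.bbox_area)
        expected = [i for i in range(n) if abs(i - key) <= p]
        assert got == expected


class TestPseudoFindings:
    def test_sentence_template_wording(self):
        labels = OrganLabels(
            "s1", ["heart", "liver"], np.array([[True, True], [False, False]])
        )
        pairs = generate_pseudo_findings(labels, mode="sentence")
        assert len(pairs) == 2
        assert pairs[0].sentence == "This CT image includes the heart"
        assert pairs[1].sentence == "This CT image includes the liver"
        assert all(p.slice_indices == (0,) for p in pairs)

    def test_word_mode_emits_bare_names(self):
        labels = OrganLabels("s1", ["heart"], np.array([[True]]))
        assert generate_pseudo_findings(labels, mode="word")[0].sentence == "heart"

    def test_no_organs_no_pairs(self):
        labels = OrganLabels("s1", ["heart"], np.zeros((3, 1), dtype=bool))
        assert generate_pseudo_findings(labels) == []

    def test_pair_count_equals_presence_sum(self, rng):
        presence = rng.random((3, 5)) < 0.5
        labels = OrganLabels("s1", [f"o{i}" for i in range(5)], presence)
        pairs = generate_pseudo_findings(labels)
        assert len(pairs) == int(presence.sum())

    def test_malformed_template(self):
        labels = OrganLabels("s1", ["heart"], np.array([[True]]))
        with pytest.raises(ConfigError):
            generate_pseudo_findings(labels, template="no placeholder", mode="sentence")


class TestBuildTrainingSet:
    def make_inputs(self, rng, n_studies=3):
        annotations, labels = [], []
        for s in range(n_studies):
            sid = f"s{s}"
            n = int(rng.integers(20, 40))
            presence = rng.random((n, 4)) < 0.4
            labels.append(OrganLabels(sid, ["a", "b", "c", "d"], presence))
            for _ in range(int(rng.integers(0, 4))):
                annotations.append(
                    annotation(
                        study=sid,
                        key=int(rng.integers(0, n)),
                        area=int(rng.integers(1, 9000)),
                        sentence=f"lesion {rng.integers(1000)}",
                    )
                )
        return annotations, labels

    def test_lesion_slice_links_closed_form(self):
        anns = [
            annotation(study="s1", key=10, area=1500),
            annotation(study="s1", key=20, area=2500),
        ]
        labels = [OrganLabels("s1", ["a"], np.zeros((50, 1), dtype=bool))]
        pairs, manifest = build_training_set(anns, labels)
        assert manifest["n_lesion_pairs"] == 2
        assert manifest["n_lesion_slice_links"] == 1 + 3  # (2p+1) per annotation

    def test_empty_annotations(self):
        labels = [OrganLabels("s1", ["a"], np.ones((5, 1), dtype=bool))]
        pairs, manifest = build_training_set([], labels)
        assert manifest["n_lesion_pairs"] == 0
        assert manifest["n_organ_pairs"] == 5

    def test_missing_study_rejected(self):
        with pytest.raises(MissingStudyError):
            build_training_set([annotation(study="ghost", area=100)], [])

    @given(seed=st.integers(0, 200))
    def test_conservation_of_counts(self, seed):
        rng = np.random.default_rng(seed)
        anns, labels = self.make_inputs(rng)
        n_by_study = {lab.study_id: lab.n_slices for lab in labels}
        pairs, manifest = build_training_set(anns, labels)
        # organ pairs conserve the presence-matrix total exactly
        assert manifest["n_organ_pairs"] == int(sum(lab.presence.sum() for lab in labels))
        # lesion slice links match brute-force enumeration
        expected_links = 0
        for ann in anns:
            p = brute_force_padding(ann.bbox_area)
            n = n_by_study[ann.study_id]
            expected_links += sum(1 for i in range(n) if abs(i - ann.key_slice) <= p)
        assert manifest["n_lesion_slice_links"] == expected_links

    def test_deterministic_byte_identical_output(self, tmp_path, rng):
        anns, labels = self.make_inputs(rng)
        out = []
        for run in range(2):
            pairs, manifest = build_training_set(anns, labels)
            path = tmp_path / f"run{run}.jsonl"
            write_pairs_jsonl(pairs, path)
            out.append((path.read_bytes(), manifest))
        assert out[0] == out[1]


class TestCsvSchemas:
    def test_round_trip_through_cohort_files(self, tmp_path, cohort):
        from keyslice.synthetic import make_fixture_cohort

        make_fixture_cohort(3, seed=5, out_dir=tmp_path)
        anns = read_annotations_csv(tmp_path / "annotations.csv")
        labels = read_organ_labels_csv(tmp_path / "organ_labels.csv")
        assert len(labels) == 3
        assert all(a.bbox_area > 0 for a in anns)
        pairs, manifest = build_training_set(anns, labels)
        assert manifest["n_organ_pairs"] == int(
            sum(lab.presence.sum() for lab in labels)
        )
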