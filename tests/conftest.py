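import warnings

import pytest

import aromapls as ap
from aromapls.synth import DEFAULT_CLASS_TREE


def make_study_peaks(seed: int):
    """Study-scale synthetic peak table with the full planted hierarchy,
    preprocessed to a Pareto-scaled matrix."""
    markers, rep_factors, split_markers = ap.plant_hierarchy_markers(
        DEFAULT_CLASS_TREE, n_features=200
    )
    cfg = ap.PeakSynthConfig(
        planted_markers=markers, replicate_factors=rep_factors, seed=seed
    )
    table, truth = ap.generate_peak_table(cfg)
    filtered, _ = ap.filter_features(table)
    scaled = ap.scale_matrix(ap.tic_normalize(filtered))
    return scaled, split_markers, truth


def make_flavor_peaks(seed: int, scale: float = 1.0):
    """Synthetic peak table with 3 positive + 4 negative planted flavor
    contributors, preprocessed; returns the scaled matrix, the feature-index
    truth signs and the class flavor means."""
    flavor_means = ap.synth.DEFAULT_VARIETY_MEANS["flavor"].to_dict()
    markers, truth = ap.plant_flavor_markers(flavor_means, scale=scale)
    cfg = ap.PeakSynthConfig(planted_markers=markers, seed=seed)
    table, _ = ap.generate_peak_table(cfg)
    filtered, _ = ap.filter_features(table)
    scaled = ap.scale_matrix(ap.tic_normalize(filtered))
    return scaled, truth, flavor_means


def recovered_splits(tree: ap.hda.HdaTree) -> set:
    """Unordered split partitions of a fitted tree (left/right symmetric)."""
    return {
        frozenset((frozenset(n.left_classes), frozenset(n.right_classes)))
        for n in tree.nodes
    }


def planted_splits(split_markers: dict) -> set:
    return {
        frozenset((frozenset(left), frozenset(right)))
        for left, right in split_markers
    }


@pytest.fixture(scope="session")
def study_peaks():
    return make_study_peaks(seed=11)


@pytest.fixture(scope="session")
def study_tree(study_peaks):
    scaled, split_markers, _ = study_peaks
    tree = ap.build_tree(
        scaled.X, scaled.classes.to_numpy(), ap.CvConfig(seed=11),
        feature_names=scaled.features,
    )
    return tree


@pytest.fixture(scope="session")
def outlier_panel():
    cfg = ap.SensorySynthConfig(n_outlier_judges=5, seed=11)
    return ap.generate_sensory_panel(cfg)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
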