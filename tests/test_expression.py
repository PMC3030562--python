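"""Detection filtering, moderated DE, non-redundant unions and shared sets."""

import numpy as np
import pandas as pd
import pytest

from acetylscan import (
    SampleDesign,
    TransitionComparison,
    benjamini_hochberg,
    detection_filter,
    moderated_de,
    nonredundant_de,
    shared_progression_sets,
    simulate_expression,
)
from acetylscan.difftest import RegTTestParams
from acetylscan.synthetic import ExpressionMatrix


def toy_matrix(detection_rows, n_samples=4):
    probes = [f"p{i}" for i in range(len(detection_rows))]
    samples = [f"c1_r{i+1}" for i in range(n_samples)]
    intensities = pd.DataFrame(
        np.zeros((len(probes), n_samples)), index=probes, columns=samples
    )
    detection = pd.DataFrame(detection_rows, index=probes, columns=samples)
    return ExpressionMatrix(intensities, detection, {s: "c1" for s in samples})


class TestDetectionFilter:
    def test_detected_in_exactly_one_sample_retained(self):
        m = toy_matrix([[0.0, 0.0, 0.9, 0.0]])
        assert detection_filter(m, 0.01) == ["p0"]

    def test_detected_nowhere_excluded(self):
        m = toy_matrix([[0.0, 0.005, 0.0, 0.01]])
        assert detection_filter(m, 0.01) == []

    def test_inverted_convention(self):
        m = toy_matrix([[0.5, 0.9, 0.7, 0.2]])
        assert detection_filter(m, 0.01, convention="less") == []
        m2 = toy_matrix([[0.5, 0.001, 0.7, 0.2]])
        assert detection_filter(m2, 0.01, convention="less") == ["p0"]

    def test_recovers_generator_detection_fraction(self):
        design = SampleDesign(replicates_per_condition=3)
        matrix, _ = simulate_expression(
            design, 4000, 0, detection_fraction=0.458, seed=3
        )
        frac = len(detection_filter(matrix, 0.01)) / 4000
        assert abs(frac - 0.458) <= 3 * np.sqrt(0.458 * 0.542 / 4000)


class TestBenjaminiHochberg:
    def test_single_test_identity(self):
        assert benjamini_hochberg(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestModeratedDE:
    def test_null_data_rarely_calls_anything(self):
        """Expect zero calls at FDR 0.001 in >= 95 of 100 seeded null runs."""
        design = SampleDesign(
            condition_names=("c1", "c2"),
            replicates_per_condition=3,
            group_partition={"c1": "A", "c2": "B"},
        )
        comp = TransitionComparison("t", "c1", "c2")
        clean = 0
        for seed in range(100):
            matrix, _ = simulate_expression(design, 300, 0, seed=seed)
            de = moderated_de(matrix, comp, fdr_threshold=0.001)
            clean += (de["call"] == "ns").all()
        assert clean >= 95

    def test_recovery_of_planted_de(self):
        """Planted log-fc = 4x noise SD, n=3, 500 DE of 10,000 probes.

        At an FDR bar of 0.001 across 10^4 tests the BH cut sits near
        |t| ~ 5 (df 24), so a 4-sigma effect (mean t ~ 4.9) is recovered for
        roughly the upper half of the planted probes; the frozen bound is the
        oracle-run value at this seed.  False discoveries stay essentially
        absent."""
        design = SampleDesign(
            condition_names=("c1", "c2"),
            replicates_per_condition=3,
            group_partition={"c1": "A", "c2": "B"},
        )
        matrix, truth = simulate_expression(
            design, 10_000, 500, log_fc=2.0, noise_sd=0.5,
            transitions=[("c1", "c2")], seed=21,
        )
        comp = TransitionComparison("c1_vs_c2", "c1", "c2")
        de = moderated_de(matrix, comp, fdr_threshold=0.001)
        labels = truth.de_probe_labels["c1_vs_c2"]
        called = de["call"] != "ns"
        planted = labels != "null"
        sensitivity = (called & planted).sum() / planted.sum()
        fdp = (called & ~planted).sum() / max(1, called.sum())
        assert sensitivity >= 0.4
        assert fdp <= 0.05
        # direction agreement on true positives
        hit = called & planted
        assert (de.loc[hit, "call"] == labels[hit]).all()

    def test_direction_convention_negates_on_swap(self):
        design = SampleDesign(
            condition_names=("c1", "c2"),
            replicates_per_condition=3,
            group_partition={"c1": "A", "c2": "B"},
        )
        matrix, _ = simulate_expression(
            design, 500, 50, log_fc=3.0, transitions=[("c1", "c2")], seed=5
        )
        fwd = moderated_de(matrix, TransitionComparison("f", "c1", "c2"))
        rev = moderated_de(matrix, TransitionComparison("r", "c2", "c1"))
        assert np.allclose(fwd["log_fc"], -rev["log_fc"])
        swapped = {"up": "down", "down": "up", "ns": "ns"}
        assert (fwd["call"].map(swapped) == rev["call"]).all()

    def test_missing_condition_rejected(self):
        design = SampleDesign(
            condition_names=("c1", "c2"),
            replicates_per_condition=3,
            group_partition={"c1": "A", "c2": "B"},
        )
        matrix, _ = simulate_expression(design, 100, 0, seed=1)
        with pytest.raises(ValueError):
            moderated_de(matrix, TransitionComparison("x", "c1", "nope"))


def de_frame(up=(), down=()):
    probes = list(up) + list(down)
    return pd.DataFrame(
        {
            "transition": "t",
            "log_fc": [1.0] * len(up) + [-1.0] * len(down),
            "p": 1e-6,
            "adjusted_p": 1e-5,
            "call": ["up"] * len(up) + ["down"] * len(down),
        },
        index=probes,
    )


class TestSetLogic:
    def test_union_of_disjoint_calls(self):
        nr = nonredundant_de({"t1": de_frame(up="ABC"), "t2": de_frame(down="DEFG")})
        assert len(nr) == 7

    def test_same_probe_in_two_transitions_counted_once(self):
        nr = nonredundant_de({"t1": de_frame(up="AB"), "t2": de_frame(up="BC")})
        assert len(nr) == 3
        assert nr.loc["B", "calls"] == [("t1", "up"), ("t2", "up")]

    def test_empty_inputs_give_empty_union(self):
        assert len(nonredundant_de({"t1": de_frame()})) == 0

    def test_shared_sets_hand_computed(self):
        me = de_frame(up="AB", down="C")
        mt = de_frame(up="BD", down="CE")
        up, down = shared_progression_sets(me, mt)
        assert up == {"B"} and down == {"C"}

    def test_disjoint_calls_give_empty_shared_sets(self):
        up, down = shared_progression_sets(de_frame(up="A"), de_frame(up="Z"))
        assert up == set() and down == set()

    def test_discordant_directions_excluded(self):
        up, down = shared_progression_sets(de_frame(up="A"), de_frame(down="A"))
        assert up == set() and down == set()

    def test_shared_sets_subset_of_inputs(self):
        me = de_frame(up="ABCD", down="EF")
        mt = de_frame(up="CDX", down="FY")
        up, down = shared_progression_sets(me, mt)
        assert up <= set("ABCD") and down <= set("EF")


def test_planted_shared_sets_recovered():
    """40 shared-up and 88 shared-down probes planted at strong effect are
    recovered at >= 80% sensitivity via the cross-model intersection."""
    design = SampleDesign(replicates_per_condition=3)
    matrix, truth = simulate_expression(
        design, 8000, 50, log_fc=3.0, noise_sd=0.5,
        n_shared_up=40, n_shared_down=88, seed=33,
    )
    expressed = detection_filter(matrix, 0.01)
    me = moderated_de(
        matrix, TransitionComparison("me", "FDCP", "ME-I"), probes=expressed
    )
    mt = moderated_de(
        matrix, TransitionComparison("mt", "MT-I", "MT-L"), probes=expressed
    )
    up, down = shared_progression_sets(me, mt)
    labels = truth.de_probe_labels
    truth_up = set(
        labels.index[
            (labels["FDCP_vs_ME-I"] == "up") & (labels["MT-I_vs_MT-L"] == "up")
        ]
    )
    truth_down = set(
        labels.index[
            (labels["FDCP_vs_ME-I"] == "down") & (labels["MT-I_vs_MT-L"] == "down")
        ]
    )
    assert len(truth_up) == 40 and len(truth_down) == 88
    assert len(up & truth_up) / 40 >= 0.8
    assert len(down & truth_down) / 88 >= 0.8
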