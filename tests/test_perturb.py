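"""The perturbation pipeline: generalize, suppress, insert."""

import numpy as np
import pandas as pd
import pytest

from ipanon import (
    EquivalentClass,
    Microdata,
    PerturbOverrides,
    PrivacyBudget,
    RandomSource,
    apply_suppression,
    counterfeit_delta,
    generalize_dataset,
    informative_score,
    noisy_threshold,
    perturb_candidate,
    sample_informative_value,
    sample_laplace,
)
from ipanon.perturb import round_half_away

BUDGET = PrivacyBudget(0.1, 0.3, 0.3, 0.3)
NOISELESS = PrivacyBudget(1e6, 1e6, 1e6, 1e6)


def make_class(counts: dict, inf="Disease", key=("k",)):
    rows = [{inf: v, "is_counterfeit": False} for v, c in counts.items() for _ in range(c)]
    return EquivalentClass(key, pd.DataFrame(rows, columns=[inf, "is_counterfeit"]), inf)


class TestGeneralizeDataset:
    def test_worked_example_classes(self, table5, table5_trees):
        """The 7-record table groups into classes of 3, 3 and 1 at the
        decade/raw-sex/zip-band node, informative values untouched."""
        classes = generalize_dataset(table5, (1, 0, 1), table5_trees)
        assert [(c.key, c.size) for c in classes] == [
            (("[10-19]", "M", "[20000-29999]"), 3),
            (("[20-29]", "F", "[30000-39999]"), 3),
            (("[60-69]", "M", "[80000-89999]"), 1),
        ]
        assert classes[0].inf_histogram == {"Gastritis": 1, "Pneumonia": 2}

    def test_bottom_node_identity(self, table5, table5_trees):
        classes = generalize_dataset(table5, (0, 0, 0), table5_trees)
        assert len(classes) == 7
        assert all(c.size == 1 for c in classes)

    def test_top_node_absorbs_all(self, table5, table5_trees):
        classes = generalize_dataset(table5, (2, 1, 2), table5_trees)
        assert len(classes) == 1
        assert classes[0].key == ("*", "*", "*")
        assert classes[0].size == 7


class TestNoisyThreshold:
    def test_noise_free_limit(self, rng):
        assert noisy_threshold(2, 1e6, rng) == pytest.approx(2, abs=1e-3)

    def test_mean_is_t(self, rng):
        n = 10**5
        r = rng.child("thr")
        draws = np.array([noisy_threshold(5, 1.0, r.child(i)) for i in range(n)])
        # Laplace scale (t-1)/eps = 4 -> sd of the mean is sqrt(2)*4/sqrt(n)
        assert abs(draws.mean() - 5) < 3 * np.sqrt(2) * 4 / np.sqrt(n)

    def test_t_below_two_rejected(self, rng):
        with pytest.raises(ValueError):
            noisy_threshold(1, 1.0, rng)


class TestSuppression:
    def test_worked_example_suppresses_singleton(self, table5, table5_trees):
        """Threshold 2 removes the size-1 class; its record re-appears fully
        starred with the informative value preserved."""
        classes = generalize_dataset(table5, (1, 0, 1), table5_trees)
        kept, bucket = apply_suppression(classes, 2.0)
        assert [c.key for c in kept] == [
            ("[10-19]", "M", "[20000-29999]"),
            ("[20-29]", "F", "[30000-39999]"),
        ]
        assert len(bucket) == 1
        row = bucket.iloc[0]
        assert (row["Age"], row["Gender"], row["Zipcode"], row["Disease"]) == ("*", "*", "*", "Stroke")

    def test_threshold_extremes(self, table5, table5_trees):
        classes = generalize_dataset(table5, (1, 0, 1), table5_trees)
        kept, bucket = apply_suppression(classes, 0.0)
        assert len(kept) == 3 and len(bucket) == 0
        kept, bucket = apply_suppression(classes, 3.0)
        assert len(kept) == 0 and len(bucket) == 7


class TestCounterfeitDelta:
    def test_noise_free_limit(self, rng):
        assert counterfeit_delta(3, 1e6, rng) == 0

    def test_symmetric_mean(self, rng):
        n = 10**5
        r = rng.child("delta")
        draws = np.array([counterfeit_delta(1, 0.3, r.child(i)) for i in range(n)])
        # Laplace sd at scale 1/0.3; rounding keeps the mean at 0.
        assert abs(draws.mean()) < 3 * np.sqrt(2) / 0.3 / np.sqrt(n)

    def test_rounding_ties_away_from_zero(self):
        assert round_half_away(0.5) == 1
        assert round_half_away(-0.5) == -1
        assert round_half_away(0.49) == 0

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            counterfeit_delta(0, 0.3, rng)
        with pytest.raises(ValueError):
            counterfeit_delta(2, 0.0, rng)

    def test_negative_delta_floors_at_empty_class(self, table5, table5_trees, rng):
        """A forced delta of -5 on a 3-record class empties it with 3 deletions."""
        key = ("[10-19]", "M", "[20000-29999]")
        ov = PerturbOverrides(threshold=2.0, deltas={key: -5})
        cand = perturb_candidate(table5, (1, 0, 1), table5_trees, BUDGET, 2, rng, overrides=ov)
        ec = {c.key: c for c in cand.classes}[key]
        assert ec.size == 0
        assert cand.n_deleted == 3


class TestInformativeScore:
    def test_present_and_absent_branches(self):
        ec = make_class({"Pneumonia": 2, "Gastritis": 1})
        domain = ["Anemia", "Diabetes", "Gastritis", "Pneumonia", "Stroke"]
        assert informative_score(ec, "Pneumonia", domain) == pytest.approx(2 / 4)
        assert informative_score(ec, "Gastritis", domain) == pytest.approx(1 / 4)
        assert informative_score(ec, "Anemia", domain) == pytest.approx(1 / (4 * 3))

    def test_empty_class_symmetric(self):
        ec = make_class({})
        domain = ["a", "b", "c", "d"]
        assert all(informative_score(ec, v, domain) == pytest.approx(1 / 4) for v in domain)

    def test_value_outside_domain_rejected(self):
        ec = make_class({"a": 1})
        with pytest.raises(ValueError):
            informative_score(ec, "zzz", ["a", "b"])


class TestSampleInformativeValue:
    def test_frequencies_match_closed_form(self, rng):
        """Empirical pick rates match the softmax of the frequency scores."""
        ec = make_class({"Pneumonia": 2, "Gastritis": 1})
        domain = ["Anemia", "Gastritis", "Pneumonia"]
        scores = np.array([1 / (4 * 1), 1 / 4, 2 / 4])
        eps = 0.3
        w = np.exp(eps * scores / 2)
        probs = w / w.sum()
        n = 10**5
        r = rng.child("inf-freq")
        counts = {v: 0 for v in domain}
        for _ in range(n):
            counts[sample_informative_value(ec, domain, eps, r)] += 1
        for v, p in zip(domain, probs):
            assert abs(counts[v] / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_tiny_epsilon_near_uniform(self, rng):
        ec = make_class({"a": 99, "b": 1})
        n = 2 * 10**4
        r = rng.child("flat")
        hits = sum(sample_informative_value(ec, ["a", "b", "c"], 1e-9, r) == "c" for _ in range(n))
        assert abs(hits / n - 1 / 3) < 4 * np.sqrt((1 / 3) * (2 / 3) / n)

    def test_dominant_value_most_likely(self, rng):
        ec = make_class({"top": 99, "rare": 1})
        domain = ["top", "rare", "absent"]
        n = 2 * 10**4
        r = rng.child("dom")
        counts = {v: 0 for v in domain}
        for _ in range(n):
            counts[sample_informative_value(ec, domain, 5.0, r)] += 1
        assert counts["top"] > counts["rare"] > 0
        assert counts["top"] > counts["absent"]

    def test_zero_epsilon_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_informative_value(make_class({"a": 1}), ["a", "b"], 0.0, rng)


class TestPerturbCandidate:
    def test_noise_free_reproduces_suppressed_table(self, table5, table5_trees, rng):
        """Fixed threshold 2 and zero deltas give exactly the hand-worked
        suppressed table, starred stroke row last."""
        ov = PerturbOverrides(threshold=2.0, deltas={})
        cand = perturb_candidate(table5, (1, 0, 1), table5_trees, BUDGET, 2, rng, overrides=ov)
        expected = pd.DataFrame(
            [
                ("[10-19]", "M", "[20000-29999]", "Gastritis"),
                ("[10-19]", "M", "[20000-29999]", "Pneumonia"),
                ("[10-19]", "M", "[20000-29999]", "Pneumonia"),
                ("[20-29]", "F", "[30000-39999]", "Anemia"),
                ("[20-29]", "F", "[30000-39999]", "Anemia"),
                ("[20-29]", "F", "[30000-39999]", "Diabetes"),
                ("*", "*", "*", "Stroke"),
            ],
            columns=["Age", "Gender", "Zipcode", "Disease"],
        )
        pd.testing.assert_frame_equal(cand.to_frame(), expected)

    def test_forced_insertions_reproduce_inserted_table(self, table5, table5_trees, rng):
        """Forcing one Gastritis and one Anemia insertion yields the
        hand-worked 9-row inserted table (as per-class row multisets)."""
        k1 = ("[10-19]", "M", "[20000-29999]")
        k2 = ("[20-29]", "F", "[30000-39999]")
        ov = PerturbOverrides(
            threshold=2.0,
            deltas={k1: 1, k2: 1},
            forced_values={k1: ["Gastritis"], k2: ["Anemia"]},
        )
        cand = perturb_candidate(table5, (1, 0, 1), table5_trees, BUDGET, 2, rng, overrides=ov)
        got = cand.to_frame()
        expected_rows = sorted(
            [
                k1 + ("Gastritis",), k1 + ("Pneumonia",), k1 + ("Pneumonia",), k1 + ("Gastritis",),
                k2 + ("Anemia",), k2 + ("Anemia",), k2 + ("Diabetes",), k2 + ("Anemia",),
                ("*", "*", "*", "Stroke"),
            ]
        )
        assert sorted(map(tuple, got.itertuples(index=False))) == expected_rows
        assert cand.n_inserted == 2
        audit = cand.to_frame(public=False)
        assert audit["is_counterfeit"].sum() == 2

    def test_empty_dataset(self, table5_trees, rng):
        empty = Microdata.build(
            pd.DataFrame(columns=["Age", "Gender", "Zipcode", "Disease"]),
            ("Age", "Gender", "Zipcode"),
            "Disease",
        )
        cand = perturb_candidate(empty, (1, 0, 1), table5_trees, BUDGET, 2, rng)
        assert cand.classes == [] and len(cand.suppressed) == 0

    def test_released_values_cover_originals_and_keys_distinct(self, table5, table5_trees, rng):
        """Ancestor property and pairwise-distinct kept keys on a noisy run.

        Every original record must land either in the kept class whose key is
        exactly its node-generalized tuple, or in the starred bucket.
        """
        node = (1, 0, 1)
        cand = perturb_candidate(table5, node, table5_trees, BUDGET, 2, rng.child("noisy"))
        keys = [c.key for c in cand.classes]
        assert len(keys) == len(set(keys))
        kept_real = sum(c.size - c.counterfeit_count for c in cand.classes) + cand.n_deleted
        assert kept_real + len(cand.suppressed) == len(table5)
        for _, row in table5.df.iterrows():
            gen = tuple(
                str(table5_trees[a].generalize(row[a], lvl))
                for a, lvl in zip(("Age", "Gender", "Zipcode"), node)
            )
            assert gen in keys or len(cand.suppressed) > 0
            # the generalized label's extent contains the raw value
            for a, lbl, lvl in zip(("Age", "Gender", "Zipcode"), gen, node):
                ext = table5_trees[a].extent(lbl)
                if isinstance(ext, tuple):
                    assert ext[0] <= int(row[a]) <= ext[1]
                else:
                    assert row[a] in ext

    def test_counterfeit_accounting(self, table5, table5_trees, rng):
        """Inserted-flag totals equal the recorded insertion count."""
        cand = perturb_candidate(
            table5, (1, 0, 1), table5_trees, PrivacyBudget(1e6, 0.5, 0.5, 0.5), 2, rng.child("acct")
        )
        flagged = sum(c.counterfeit_count for c in cand.classes)
        assert flagged == cand.n_inserted

    def test_deterministic_under_seed(self, table5, table5_trees):
        a = perturb_candidate(table5, (1, 0, 1), table5_trees, BUDGET, 2, RandomSource(5))
        b = perturb_candidate(table5, (1, 0, 1), table5_trees, BUDGET, 2, RandomSource(5))
        pd.testing.assert_frame_equal(a.to_frame(public=False), b.to_frame(public=False))
        assert a.noisy_threshold == b.noisy_threshold


class TestInsertionStageDP:
    def test_released_size_ratio_bound(self, rng):
        """Monte-Carlo check of the e^eps bound for the noisy class size.

        For neighboring class sizes n and n+1, every released-size outcome
        probability must satisfy the ratio bound within 3-sigma sampling
        error, in both directions.
        """
        eps, n, trials = 1.0, 3, 10**6
        r = rng.child("dp")

        def released_sizes(base, tag):
            noise = sample_laplace(1.0 / eps, r.child(tag), size=trials)
            return np.maximum(0, base + round_half_away(noise)).astype(int)

        a = released_sizes(n, "a")
        b = released_sizes(n + 1, "b")
        outcomes = np.union1d(np.unique(a), np.unique(b))
        for s in outcomes:
            pa = (a == s).mean()
            pb = (b == s).mean()
            if max(pa, pb) < 1e-4:
                continue
            sig = np.sqrt(pa * (1 - pa) / trials + np.exp(2 * eps) * pb * (1 - pb) / trials)
            assert pa <= np.exp(eps) * pb + 3 * sig
            sig = np.sqrt(pb * (1 - pb) / trials + np.exp(2 * eps) * pa * (1 - pa) / trials)
            assert pb <= np.exp(eps) * pa + 3 * sig
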