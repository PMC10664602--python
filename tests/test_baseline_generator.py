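import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import VALID_POOL
from retroval.baseline_generator import (
    MarkovSmilesModel,
    TokenizeError,
    region_nll_summary,
    tokenize,
)


class TestTokenize:
    def test_chlorine(self):
        assert tokenize("CCl") == ["C", "Cl"]

    def test_bracket_atom(self):
        assert tokenize("C[nH]1cccc1") == [
            "C", "[nH]", "1", "c", "c", "c", "c", "1",
        ]

    def test_ring_closure_percent(self):
        assert tokenize("C%12CC%12") == ["C", "%12", "C", "C", "%12"]

    def test_dangling_bracket(self):
        with pytest.raises(TokenizeError):
            tokenize("C[nH")

    @given(st.sampled_from(VALID_POOL))
    @settings(max_examples=20, deadline=None)
    def test_roundtrip(self, smi):
        assert "".join(tokenize(smi)) == smi


class TestFit:
    def test_hand_counted_transitions(self):
        m = MarkovSmilesModel(order=1, smoothing=0.0).fit(["CC", "CC"])
        dist = dict(zip(m.vocab, m.context_distribution(("^",))))
        assert dist["C"] == 1.0
        dist = dict(zip(m.vocab, m.context_distribution(("C",))))
        assert dist["C"] == 0.5 and dist["$"] == 0.5

    def test_counts_sum_to_transitions(self):
        corpus = ["CCO", "CCN"]
        m = MarkovSmilesModel(order=2, smoothing=0.0).fit(corpus)
        total = sum(sum(c.values()) for c in m.counts.values())
        # each molecule contributes len(tokens)+1 transitions (end token)
        assert total == sum(len(tokenize(s)) + 1 for s in corpus)

    def test_single_molecule_high_order_reproduces(self):
        m = MarkovSmilesModel(order=5, smoothing=0.0).fit(["c1ccccc1"])
        assert m.sample(5, seed=1) == ["c1ccccc1"] * 5

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError):
            MarkovSmilesModel().fit([])


class TestNll:
    def test_two_string_toy(self):
        m = MarkovSmilesModel(order=1, smoothing=0.0).fit(["CC", "CC"])
        assert m.nll("CC") == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_deterministic_path_zero(self):
        m = MarkovSmilesModel(order=4, smoothing=0.0).fit(["CCO"])
        assert m.nll("CCO") == 0.0

    def test_finite_with_smoothing(self):
        m = MarkovSmilesModel(order=2, smoothing=0.01).fit(["CCO"])
        assert math.isfinite(m.nll("OCC"))

    def test_infinite_without_smoothing(self):
        m = MarkovSmilesModel(order=1, smoothing=0.0).fit(["CC"])
        assert m.nll("CN") == math.inf


class TestFocus:
    def test_lambda_zero_identity(self):
        m = MarkovSmilesModel(order=1, smoothing=0.01).fit(["CCO", "CCN"])
        f = m.focus(["CCC"], lam=0.0)
        for smi in ("CCO", "CCN", "CCC"):
            assert f.nll(smi) == pytest.approx(m.nll(smi), abs=1e-12)

    def test_lambda_one_concentrates(self):
        m = MarkovSmilesModel(order=2, smoothing=0.001).fit(
            ["CCO", "CCN", "c1ccccc1"]
        )
        f = m.focus(["CCCCC"], lam=1.0)
        assert f.nll("CCCCC") < m.nll("CCCCC")

    def test_focus_nll_non_increasing_in_lambda(self):
        # grid of lambda values, direct NLL evaluation
        m = MarkovSmilesModel(order=1, smoothing=0.01).fit(
            ["CCO", "CCN", "CCCC", "c1ccccc1"]
        )
        focus_corpus = ["CCCCCC", "CCCC"]
        prev = math.inf
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            f = m.focus(focus_corpus, lam)
            cur = float(np.mean([f.nll(s) for s in focus_corpus]))
            assert cur <= prev + 1e-9
            prev = cur

    def test_empty_focus_errors(self):
        m = MarkovSmilesModel().fit(["CC"])
        with pytest.raises(ValueError):
            m.focus([], 0.5)


class TestSample:
    def test_same_seed_identical(self):
        m = MarkovSmilesModel(order=2, smoothing=0.01).fit(VALID_POOL)
        assert m.sample(50, seed=9) == m.sample(50, seed=9)

    def test_validity_beats_random_tokens(self, fixture_suite):
        from retroval.chem_io import is_valid_smiles, load_generated_set

        corpus, _ = load_generated_set(fixture_suite["pretraining_corpus"])
        corpus = corpus[:200]
        m = MarkovSmilesModel(order=3, smoothing=0.01).fit(corpus)
        samples = m.sample(300, seed=2)
        valid_markov = np.mean([is_valid_smiles(s) for s in samples])
        # random-token baseline at the same length distribution
        rng = np.random.default_rng(2)
        vocab = [t for t in m.vocab if t != "$"]
        baseline = [
            "".join(rng.choice(vocab, size=max(len(s), 1)))
            for s in samples
        ]
        valid_random = np.mean([is_valid_smiles(s) for s in baseline])
        assert valid_markov > valid_random


class TestNormalization:
    def test_distributions_sum_to_one(self):
        for smoothing in (0.0, 0.01, 1.0):
            m = MarkovSmilesModel(order=2, smoothing=smoothing).fit(
                ["CCO", "CCN", "c1ccccc1"]
            )
            for ctx in list(m.counts)[:20]:
                assert m.context_distribution(ctx).sum() == pytest.approx(
                    1.0, abs=1e-12
                )
            f = m.focus(["CCO"], 0.5)
            for ctx in list(f.counts)[:20]:
                assert f.context_distribution(ctx).sum() == pytest.approx(
                    1.0, abs=1e-12
                )


class TestSamplingNllConsistency:
    def test_chi_square_two_string_toy(self):
        """Empirical frequencies converge to exp(-NLL), n=10,000, fixed seed."""
        from scipy.stats import chisquare

        m = MarkovSmilesModel(order=1, smoothing=0.0).fit(
            ["CC", "CC", "CC", "CCC"]
        )
        n = 10_000
        samples = m.sample(n, max_len=50, seed=11)
        freq = Counter(samples)
        top = [s for s, _ in freq.most_common(4)]
        expected_p = [math.exp(-m.nll(s)) for s in top]
        observed = [freq[s] for s in top]
        # tail bucket keeps totals equal
        observed.append(n - sum(observed))
        expected = [p * n for p in expected_p]
        expected.append(n - sum(expected))
        _, pvalue = chisquare(observed, expected)
        assert pvalue > 0.01


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        m = MarkovSmilesModel(order=2, smoothing=0.01).fit(VALID_POOL)
        f = m.focus(["CCO", "CCN"], 0.6)
        p = tmp_path / "model.json"
        f.save(p)
        loaded = MarkovSmilesModel.load(p)
        for smi in VALID_POOL[:5]:
            assert loaded.nll(smi) == pytest.approx(f.nll(smi), abs=1e-12)
        assert loaded.sample(20, seed=4) == f.sample(20, seed=4)


class TestRegionNllSummary:
    def test_focused_lowers_alpha_nll(self, public_labelled):
        corpus = [r.smiles_canonical for r in public_labelled.records]
        prior = MarkovSmilesModel(order=2, smoothing=0.01).fit(corpus)
        focused = prior.focus(public_labelled.region_smiles("alpha"), 0.8)
        df = region_nll_summary(
            {"prior": prior, "focused": focused}, public_labelled
        ).set_index(["model", "region"])
        assert (
            df.loc[("focused", "alpha"), "mean_nll"]
            < df.loc[("prior", "alpha"), "mean_nll"]
        )
        assert len(df) == 6  # 2 models x 3 populated regions

    def test_training_set_deterministic_zero(self):
        from retroval.chem_io import MoleculeRecord
        from retroval.stratify import LabelledDataset

        recs = [
            MoleculeRecord(
                id=f"r{i}", smiles_raw=s, smiles_canonical=s,
                pxc50=8.0, source_row=i,
            )
            for i, s in enumerate(["CCO"])
        ]
        ds = LabelledDataset(
            records=recs,
            stage=["late"],
            activity_class=["ultra_high"],
            region=["gamma"],
        )
        model = MarkovSmilesModel(order=4, smoothing=0.0).fit(["CCO"])
        df = region_nll_summary({"m": model}, ds)
        assert df.iloc[0]["mean_nll"] == 0.0
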