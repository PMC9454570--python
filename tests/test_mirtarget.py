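"""Prediction consensus, seed matching and the anti-correlation filter."""

import numpy as np
import pandas as pd
import pytest

from mirrescue.matrix import ExpressionMatrix
from mirrescue.mirtarget import (MiRTargetRecord, PredictionError,
                                 anticorrelate, filter_pairs,
                                 load_predictions, records_table,
                                 seed_match, targets_by_mirna)
from mirrescue.simulate import (SimulationConfig, simulate_mirna,
                                simulate_mrna, simulate_predictions)


def _table(rows, source):
    return pd.DataFrame([{"mirna": m, "gene": g, "source": source}
                         for m, g in rows])


class TestLoadPredictions:
    def test_same_pair_in_five_tables_dedups(self):
        tables = [_table([("m1", "g1")], f"alg{k}") for k in range(5)]
        recs = load_predictions(tables)
        assert len(recs) == 1
        assert len(recs[0].sources) == 5

    def test_min_support_drops_singletons(self):
        tables = [_table([("m1", "g1"), ("m1", "g2")], "a"),
                  _table([("m1", "g1")], "b")]
        recs = load_predictions(tables, min_support=2)
        assert [(r.mirna, r.gene) for r in recs] == [("m1", "g1")]

    def test_union_matches_set_algebra_oracle(self, small_dataset):
        cfg, _, _, truth, tables = small_dataset
        recs = load_predictions(tables, min_support=1)
        oracle = set()
        for t in tables:
            oracle |= set(zip(t["mirna"], t["gene"]))
        assert {(r.mirna, r.gene) for r in recs} == oracle
        # five-source consensus equals the set intersection
        recs5 = load_predictions(tables, min_support=5)
        inter = set.intersection(*(set(zip(t["mirna"], t["gene"]))
                                   for t in tables))
        assert {(r.mirna, r.gene) for r in recs5} == inter

    def test_malformed_rows_skipped_and_all_bad_is_error(self):
        bad = pd.DataFrame({"mirna": ["m1", None], "gene": ["g1", "g2"],
                            "source": ["a", "a"]})
        recs = load_predictions([bad])
        assert len(recs) == 1
        all_bad = pd.DataFrame({"mirna": [None], "gene": ["g"],
                                "source": ["a"]})
        with pytest.raises(PredictionError):
            load_predictions([all_bad])


class TestSeedMatch:
    MIRNA = "UGGAAUGUAAAGAAGUAUGUAU"  # positions 2-8 = GGAAUGU

    def test_constructed_8mer_site(self):
        # reverse complement of positions 2-8 (GGAAUGU) is ACATTCC;
        # append A opposite position 1 for the 8mer
        utr = "CCCC" + "ACATTCC" + "A" + "GGGG"
        sites = seed_match(self.MIRNA, utr)
        assert sites == [{"type": "8mer", "start": 4, "end": 12}]

    def test_site_type_hierarchy(self):
        core = "ACATTCC"  # 7mer-m8 match
        assert seed_match(self.MIRNA, "GG" + core + "G")[0]["type"] == \
            "7mer-m8"
        assert seed_match(self.MIRNA, "GG" + core[1:] + "A")[0]["type"] == \
            "7mer-A1"
        assert seed_match(self.MIRNA, "GG" + core[1:] + "G")[0]["type"] == \
            "6mer"

    def test_no_complementary_6mer_gives_empty_list(self):
        assert seed_match(self.MIRNA, "GGGGGGGGGGGG") == []

    def test_bad_alphabet_is_an_error(self):
        with pytest.raises(PredictionError):
            seed_match(self.MIRNA, "ACGTX")

    def test_random_utr_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(10)
        utr = "".join(rng.choice(list("ACGT"), size=1000))
        sites = seed_match(self.MIRNA, utr)
        core6 = "CATTCC"  # revcomp of positions 2-7
        naive = sum(1 for i in range(len(utr) - 5)
                    if utr[i:i + 6] == core6)
        assert len(sites) == naive


def _paired_matrices(x_rows, y_rows, mirna_ids, gene_ids):
    samples = [f"s{i}" for i in range(len(x_rows[0]))]
    groups = pd.Series("C", index=samples)
    mi = ExpressionMatrix(values=pd.DataFrame(x_rows, index=mirna_ids,
                                              columns=samples),
                          groups=groups)
    mr = ExpressionMatrix(values=pd.DataFrame(y_rows, index=gene_ids,
                                              columns=samples),
                          groups=groups)
    return mi, mr


class TestAnticorrelate:
    def test_perfect_anticorrelation(self):
        mi, mr = _paired_matrices([[1.0, 2.0, 3.0]], [[3.0, 2.0, 1.0]],
                                  ["m1"], ["g1"])
        recs = anticorrelate([MiRTargetRecord("m1", "g1", frozenset())],
                             mi, mr)
        assert recs[0].r == pytest.approx(-1.0)
        assert recs[0].p_neg == pytest.approx(0.0, abs=1e-12)

    def test_identical_vectors_never_retained(self):
        mi, mr = _paired_matrices([[1.0, 2.0, 3.0, 4.0]],
                                  [[1.0, 2.0, 3.0, 4.0]], ["m1"], ["g1"])
        recs = anticorrelate([MiRTargetRecord("m1", "g1", frozenset())],
                             mi, mr)
        assert recs[0].r == pytest.approx(1.0)
        assert recs[0].p_neg > 0.99
        assert filter_pairs(recs) == []

    def test_constant_vector_excluded_from_bh_family(self):
        mi, mr = _paired_matrices([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                                  [[3.0, 2.0, 1.0], [3.0, 2.0, 1.0]],
                                  ["m1", "m2"], ["g1", "g2"])
        recs = anticorrelate(
            [MiRTargetRecord("m1", "g1", frozenset()),
             MiRTargetRecord("m2", "g2", frozenset())], mi, mr)
        assert np.isnan(recs[0].r) and np.isnan(recs[0].q)
        # BH family of size 1: q equals the raw one-sided p
        assert recs[1].q == pytest.approx(recs[1].p_neg)

    def test_too_few_shared_samples_is_an_error(self):
        mi, mr = _paired_matrices([[1.0, 2.0]], [[2.0, 1.0]],
                                  ["m1"], ["g1"])
        with pytest.raises(PredictionError):
            anticorrelate([MiRTargetRecord("m1", "g1", frozenset())],
                          mi, mr)

    def test_null_p_values_match_permutation_oracle(self):
        """One-sided correlation p-values from the t transform agree in
        distribution with a permutation oracle under the null."""
        rng = np.random.default_rng(11)
        n, pairs = 12, 200
        X = rng.normal(size=(pairs, n))
        Y = rng.normal(size=(pairs, n))
        mi, mr = _paired_matrices(X, Y, [f"m{i}" for i in range(pairs)],
                                  [f"g{i}" for i in range(pairs)])
        recs = anticorrelate(
            [MiRTargetRecord(f"m{i}", f"g{i}", frozenset())
             for i in range(pairs)], mi, mr)
        p_t = np.array([r.p_neg for r in recs])
        # permutation oracle on each pair (null r distribution shared)
        perm_r = []
        x = X[0]
        for _ in range(2000):
            perm_r.append(np.corrcoef(x, rng.permutation(Y[0]))[0, 1])
        perm_r = np.array(perm_r)
        for q in (0.1, 0.25, 0.5):
            r_obs = np.quantile([r.r for r in recs], q)
            p_perm = (perm_r <= r_obs).mean()
            assert abs(q - p_perm) < 0.08  # MC + sampling error
        # calibration: p-values uniform -> mean ~ 0.5
        assert abs(p_t.mean() - 0.5) < 0.08


class TestFilterPairs:
    def _rec(self, r, q):
        rec = MiRTargetRecord("m", "g", frozenset())
        rec.r, rec.q = r, q
        return rec

    @pytest.mark.parametrize("r,q,kept", [
        (-0.9, 0.01, True),
        (-0.6, 0.2, False),   # FDR fails
        (-0.5, 0.01, False),  # boundary: strictly below -0.5 required
        (-0.51, 0.05, False),  # boundary: q strictly below 0.05 required
        (0.9, 0.001, False),
    ])
    def test_retention_rule(self, r, q, kept):
        assert bool(filter_pairs([self._rec(r, q)])) is kept

    def test_order_invariance(self):
        recs = [self._rec(-0.9, 0.01), self._rec(-0.2, 0.5),
                self._rec(-0.7, 0.04)]
        a = {(r.r, r.q) for r in filter_pairs(recs)}
        b = {(r.r, r.q) for r in filter_pairs(list(reversed(recs)))}
        assert a == b


def test_planted_pair_recovery_single_dataset():
    """beta=1, sigma=0.3, 12 samples, decoy_rate=1: planted pairs are
    retained with high sensitivity and essentially no decoys."""
    cfg = SimulationConfig(n_genes=400, n_mirnas=120, n_true_pairs=40,
                           beta=1.0, sigma=0.3, dropout_p=0.0, seed=23)
    mrna, truth = simulate_mrna(cfg)
    mirna, truth = simulate_mirna(cfg, truth, mrna)
    tables = simulate_predictions(truth, decoy_rate=1.0, n_sources=1,
                                  seed=23)
    recs = anticorrelate(load_predictions(tables), mirna, mrna)
    retained = filter_pairs(recs)
    kept = {(r.mirna, r.gene) for r in retained}
    sens = len(kept & truth.pair_set) / len(truth.pair_set)
    fdp = len(kept - truth.pair_set) / max(len(kept), 1)
    assert sens >= 0.9
    assert fdp <= 0.1
    table = records_table(recs)
    assert table["retained"].sum() == len(retained)
    by_mirna = targets_by_mirna(retained)
    assert sum(len(v) for v in by_mirna.values()) == len(retained)
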