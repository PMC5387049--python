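"""Exact hypergeometric enrichment tests and the splicing-code table,
validated against integer-arithmetic enumeration."""

from math import comb

import numpy as np
import pytest

from splicecode.consensus import PairedConsensus
from splicecode.enrichment import (
    ContingencyCell,
    SplicingCodeTable,
    benjamini_hochberg,
    build_code_table,
    fisher_enrichment,
    hypergeom_tails,
)
from splicecode.exon_classifier import IntronClass, enumerate_intron_classes


def exact_tails(N, K, n, a):
    """Hypergeometric tails by exact integer enumeration."""
    denom = comb(N, n)
    lo, hi = max(0, K + n - N), min(K, n)
    pmf = {k: comb(K, k) * comb(N - K, n - k) for k in range(lo, hi + 1)}
    p_up = sum(v for k, v in pmf.items() if k >= a) / denom
    p_down = sum(v for k, v in pmf.items() if k <= a) / denom
    return p_up, p_down


def cell(N, K, n, a):
    return ContingencyCell(a=a, b=K - a, c_=n - a, d=N - K - n + a)


class TestHypergeomTails:
    def test_full_overlap_small_universe(self):
        # universe 10, class 5, motif 5, overlap 5: only 1 of C(10,5)
        # configurations reaches the observed cell
        p_up, _ = hypergeom_tails(cell(10, 5, 5, 5))
        assert p_up == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_overlap_lower_tail(self):
        _, p_down = hypergeom_tails(cell(20, 4, 10, 0))
        assert p_down == pytest.approx(210 / 4845, rel=1e-12)

    def test_degenerate_motif_margin(self):
        p_up, p_down = hypergeom_tails(cell(50, 0, 10, 0))
        assert p_up == 1.0
        assert p_down == 1.0

    def test_tails_overlap_at_observed_cell(self):
        p_up, p_down = hypergeom_tails(cell(40, 12, 9, 3))
        assert p_up + p_down >= 1.0

    def test_monotone_in_overlap(self):
        ups = [hypergeom_tails(cell(60, 20, 15, a))[0] for a in range(0, 16)]
        assert all(x >= y for x, y in zip(ups, ups[1:]))

    def test_agrees_with_enumeration_for_all_small_tables(self):
        """Every margin with total <= 60, against integer arithmetic."""
        from scipy.stats import hypergeom

        for N in range(1, 61):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    lo, hi = max(0, K + n - N), min(K, n)
                    a = np.arange(lo, hi + 1)
                    up = hypergeom.sf(a - 1, N, K, n)
                    down = hypergeom.cdf(a, N, K, n)
                    denom = comb(N, n)
                    pmf = np.array(
                        [comb(K, k) * comb(N - K, n - k) for k in range(lo, hi + 1)],
                        dtype=float,
                    )
                    exact_up = pmf[::-1].cumsum()[::-1] / denom
                    exact_down = pmf.cumsum() / denom
                    assert np.allclose(up, exact_up, rtol=1e-9, atol=1e-300)
                    assert np.allclose(down, exact_down, rtol=1e-9, atol=1e-300)

    def test_extreme_pvalues_do_not_underflow_to_garbage(self):
        # genome-scale effect: motif perfectly concentrated in one class
        p_up, _ = hypergeom_tails(cell(200000, 500, 2000, 500))
        assert 0.0 <= p_up < 1e-100


def make_maps(rng, n, motifs, classes, motif_p=0.5):
    """Random independent assignment/label maps over a shared universe."""
    assignments, labels = {}, {}
    pcs = [
        PairedConsensus(f"gu{m:02d}", "ag", count=0, rank=m + 1)
        for m in range(motifs)
    ]
    class_pool = enumerate_intron_classes()[:classes]
    for i in range(n):
        iid = f"i{i}"
        assignments[iid] = (
            pcs[rng.integers(motifs)] if rng.random() < motif_p else None
        )
        labels[iid] = class_pool[rng.integers(classes)]
    return assignments, labels


class TestFisherEnrichment:
    def test_margin_conservation(self):
        rng = np.random.default_rng(0)
        assignments, labels = make_maps(rng, 2000, 5, 8)
        entries = fisher_enrichment(assignments, labels)
        by_motif = {}
        for e in entries:
            by_motif.setdefault(e.motif, []).append(e)
        for motif, es in by_motif.items():
            total_a = sum(e.cell.a for e in es)
            expected = sum(1 for pc in assignments.values() if pc and pc.motif == motif)
            assert total_a == expected
            assert all(e.cell.total == 2000 for e in es)

    def test_mismatched_universes_rejected(self):
        rng = np.random.default_rng(1)
        assignments, labels = make_maps(rng, 50, 2, 3)
        del labels["i0"]
        with pytest.raises(ValueError):
            fisher_enrichment(assignments, labels)
        with pytest.raises(ValueError):
            fisher_enrichment({}, {})

    def test_type_i_error_control_on_null_data(self):
        """Independent motifs/classes: flagged fraction stays near alpha."""
        flagged = tested = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            assignments, labels = make_maps(rng, 10_000, 20, 10)
            entries = fisher_enrichment(assignments, labels, alpha=0.001)
            live = [e for e in entries if e.cell.class_count > 0]
            tested += len(live)
            flagged += sum(
                e.significant_up or e.significant_down for e in live
            )
        assert flagged / tested <= 0.005


class TestCodeTable:
    def test_planted_association_is_reported(self):
        # motif planted exclusively in S-S introns (500 of 5000)
        ss = IntronClass("S-S")
        rr = IntronClass("R-R")
        pc = PairedConsensus("guaa", "ag", count=500, rank=5)
        assignments = {}
        labels = {}
        for i in range(5000):
            iid = f"i{i}"
            if i < 500:
                assignments[iid], labels[iid] = pc, ss
            elif i < 1000:
                assignments[iid], labels[iid] = None, ss
            else:
                assignments[iid], labels[iid] = None, rr
        entries = fisher_enrichment(assignments, labels)
        code = build_code_table(entries)
        assert 5 in code.enriched[ss]
        assert code.enriched_classes(5) == {ss}
        # exact oracle for the planted cell
        e = next(x for x in entries if x.intron_class is ss)
        assert e.p_up == pytest.approx(exact_tails(5000, 500, 1000, 500)[0], rel=1e-9)

    def test_alpha_zero_flags_nothing(self):
        rng = np.random.default_rng(2)
        assignments, labels = make_maps(rng, 500, 3, 4)
        entries = fisher_enrichment(assignments, labels)
        code = build_code_table(entries, alpha=0.0)
        assert all(not ranks for ranks in code.enriched.values())
        assert all(not ranks for ranks in code.depleted.values())

    def test_tsv_round_trip(self, tmp_path, table2):
        path = tmp_path / "code.tsv"
        table2.to_tsv(path)
        back = SplicingCodeTable.from_tsv(path)
        assert back.enriched == table2.enriched
        assert back.depleted == table2.depleted

    def test_grid_renderer_shows_all_rows(self, table2):
        grid = table2.render_grid()
        lines = grid.splitlines()
        assert lines[0].split("\t") == ["UP", "A3", "A5", "ME", "R", "S", "APA"]
        assert len(lines) == 13  # header + 6 upstream types x 2 lines


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    p = rng.uniform(size=50).tolist()
    ours = benjamini_hochberg(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)
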