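"""G4 scanner: run extraction, greedy counting, oracle equivalence, monotonicity."""

import numpy as np
import pytest

from minisatkit import CEB1, CEB25, HRAS1, TandemArray
from minisatkit.g4scan import (
    G4ScanParams,
    annotate_catalog,
    count_g4,
    find_g_runs,
    scan_g4,
)
from minisatkit.genome_dist import MinisatelliteRecord


# ---------------------------------------------------------------- primitives

def test_g_runs_of_ceb1():
    assert find_g_runs(CEB1.sequence, 3) == [(0, 6), (7, 3), (11, 3), (32, 3)]


def test_g_runs_are_maximal():
    assert find_g_runs("GGGGGG", 3) == [(0, 6)]
    assert find_g_runs("AAAA", 3) == []
    assert find_g_runs("GGGAGGG", 3) == [(0, 3), (4, 3)]


def test_default_params_derive_loop_max_16():
    assert G4ScanParams().loop_max == 16
    assert G4ScanParams(window_max=40).loop_max == 26
    assert G4ScanParams(window_max=100).loop_max == 86
    with pytest.raises(ValueError):
        G4ScanParams(window_max=14)  # cannot fit 4x3 G with 1-nt loops


# ---------------------------------------------------------------- counting

@pytest.mark.parametrize(
    "motif, copies, expected",
    [
        (HRAS1, 1, 0),
        (HRAS1, 5, 0),
        (CEB25, 1, 1),
        (CEB25, 2, 2),
        (CEB25, 3, 3),
        (CEB1, 1, 0),
        (CEB1, 2, 1),
        (CEB1, 3, 2),
        (CEB1, 6, 5),
    ],
)
def test_motif_and_array_counts(motif, copies, expected):
    """HRAS1 never qualifies; CEB25 hits scale with copies; CEB1 hits span junctions."""
    n, _ = count_g4(TandemArray(motif, copies).sequence)
    assert n == expected


def test_ceb1_dimer_hit_spans_the_motif_junction():
    _, hits = count_g4(TandemArray(CEB1, 2).sequence)
    (h,) = hits
    assert h.start == 32 and h.end == 53  # crosses the 39-nt boundary
    assert h.tract_starts == (32, 39, 46, 50)


def test_ceb25_monomer_hit_tracts():
    _, hits = count_g4(CEB25.sequence)
    (h,) = hits
    assert h.tract_starts == (2, 6, 18, 22)
    assert h.span <= 30


def test_minimal_span_rule_long_first_tract():
    # 6-G first tract: only its 3-G suffix needs to fit the window
    seq = "GGGGGG" + "A" * 14 + "GGGTGGGTGGG"
    n, hits = count_g4(seq)
    assert n == 1
    assert hits[0].tract_lengths[0] == 6


def test_hits_are_pairwise_disjoint():
    seq = TandemArray(CEB25, 8).sequence
    _, hits = count_g4(seq)
    spans = sorted((h.start, h.end) for h in hits)
    assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def test_strand_modes():
    # a C-free sequence has no G-runs on its reverse complement
    n_given, _ = count_g4(CEB25.sequence, strand_mode="given")
    n_both, hits = count_g4(CEB25.sequence, strand_mode="both")
    assert n_given == n_both == 1
    # the reverse complement of a G4-bearing sequence scores on the other strand
    from minisatkit.motifs import reverse_complement

    n_rc, hits_rc = count_g4(reverse_complement(TandemArray(CEB25, 2).sequence),
                             strand_mode="both")
    assert n_rc == 2
    assert all(h.strand == "reverse_complement" for h in hits_rc)
    with pytest.raises(ValueError):
        count_g4("GGG", strand_mode="watson")


# ---------------------------------------------------------------- oracle

def _oracle_max_disjoint(seq: str, params: G4ScanParams) -> int:
    """Brute-force maximum-cardinality disjoint selection of valid windows.

    Enumerates every set of n_tracts consecutive maximal G-runs satisfying
    the loop and (minimal-span) window rules, then takes the maximum number
    of pairwise-disjoint candidates by dynamic programming over candidates
    sorted by end.
    """
    runs = find_g_runs(seq, params.tract_min_g)
    n, t = params.n_tracts, params.tract_min_g
    cands = []
    for i in range(len(runs) - n + 1):
        chosen = runs[i : i + n]
        ok = all(
            params.loop_min <= s1 - (s0 + l0) <= params.loop_max
            for (s0, l0), (s1, _l) in zip(chosen, chosen[1:])
        )
        span = (chosen[-1][0] + t) - (chosen[0][0] + chosen[0][1] - t)
        if ok and span <= params.window_max:
            cands.append((chosen[0][0], chosen[-1][0] + chosen[-1][1]))
    cands.sort(key=lambda c: c[1])
    best = [0] * (len(cands) + 1)
    for k, (s, _e) in enumerate(cands, 1):
        take = 1
        for j in range(k - 1, 0, -1):
            if cands[j - 1][1] <= s:
                take = best[j] + 1
                break
        best[k] = max(best[k - 1], take)
    return best[-1]


def test_greedy_count_equals_bruteforce_maximum():
    """500 random and tandem sequences up to 2 kb: greedy = optimal."""
    rng = np.random.default_rng(2024)
    params = G4ScanParams()
    motifs = [CEB1.sequence, CEB25.sequence, HRAS1.sequence]
    for trial in range(500):
        kind = trial % 3
        if kind == 0:  # G-enriched random sequence
            L = int(rng.integers(30, 2000))
            seq = "".join(rng.choice(list("ACGT"), size=L,
                                     p=[0.15, 0.15, 0.5, 0.2]))
        elif kind == 1:  # tandem array of a study motif
            m = motifs[int(rng.integers(0, 3))]
            seq = m * int(rng.integers(1, 2000 // len(m)))
        else:  # tandem array of a random short motif
            m = "".join(rng.choice(list("ACGT"), size=int(rng.integers(10, 60)),
                                   p=[0.1, 0.1, 0.6, 0.2]))
            seq = m * int(rng.integers(2, 25))
        n, _ = count_g4(seq, params)
        assert n == _oracle_max_disjoint(seq, params), seq


def test_count_monotone_in_window_size():
    rng = np.random.default_rng(7)
    for _ in range(50):
        L = int(rng.integers(50, 800))
        seq = "".join(rng.choice(list("ACGT"), size=L, p=[0.1, 0.1, 0.6, 0.2]))
        counts = [count_g4(seq, G4ScanParams(window_max=w))[0]
                  for w in (30, 40, 50, 100)]
        assert counts == sorted(counts)


# ---------------------------------------------------------------- catalog

def _record(seq, motif_size=39):
    return MinisatelliteRecord(
        chrom="chr1", start=1, end=len(seq), motif_size=motif_size,
        copy_number=len(seq) / motif_size, array_length=len(seq),
        gc_content=0.6, sequence=seq,
    )


def test_annotate_catalog_counts_and_strand():
    recs = [
        _record(TandemArray(CEB25, 3).sequence, 52),
        _record("A" * 200, 20),
        _record(TandemArray(CEB1, 4, orientation="C").sequence, 39),
    ]
    annotate_catalog(recs)
    assert recs[0].g4_counts[30] == 3 and recs[0].g4_strand == "G"
    assert recs[1].g4_counts == {30: 0, 40: 0, 50: 0, 100: 0}
    assert recs[1].g4_strand is None
    assert recs[2].g4_counts[30] == 3 and recs[2].g4_strand == "C"
    for rec in recs:
        counts = [rec.g4_counts[w] for w in (30, 40, 50, 100)]
        assert counts == sorted(counts)


def test_annotate_catalog_skips_sequenceless_records():
    rec = MinisatelliteRecord(chrom="chr1", start=1, end=100, motif_size=20,
                              copy_number=5, array_length=100, gc_content=0.5)
    out = annotate_catalog([rec])
    assert out[0].g4_counts == {}
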