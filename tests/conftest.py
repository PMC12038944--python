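import numpy as np
import pytest

import founderdel as fd


@pytest.fixture(scope="session")
def default_locus():
    ref = fd.build_locus(seed=1)
    ref.validate()
    return ref


@pytest.fixture(scope="session")
def default_deletion(default_locus):
    return fd.apply_deletion(default_locus)


@pytest.fixture(scope="session")
def small_panel():
    """A 20k-individual panel with perfect proxies (no recombination erosion
    at default distances matters at this scale)."""
    return fd.simulate_panel(fd.PanelConfig(N=20_000), seed=11)


def oracle_local_score(read: str, ref: str, sc: fd.Scoring) -> tuple:
    """Plain-python affine-gap local DP; returns (best, M, Mr) tables.

    Same recurrence convention as the production aligner (gaps open from M
    only, zero floor on M) but computed with naive loops, independent of the
    vectorized implementation.
    """
    NEG = -(10**9)
    n, m = len(read), len(ref)
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
            M[i][j] = max(0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i][j - 1] + sc.gap_open, Ix[i][j - 1] + sc.gap_extend)
            Iy[i][j] = max(M[i - 1][j] + sc.gap_open, Iy[i - 1][j] + sc.gap_extend)
            best = max(best, M[i][j])
    return best, M


def oracle_split_score(read: str, ref: str, sc: fd.Scoring, exhaustive: bool = True) -> int:
    """Best prefix+suffix score with one reference gap >= min_del_len,
    enumerating every (read split, left end, right start) placement."""
    n, m = len(read), len(ref)
    _, Mf = oracle_local_score(read, ref, sc)
    _, Mr = oracle_local_score(read[::-1], ref[::-1], sc)
    best = -(10**9)
    for i in range(1, n):
        if exhaustive:
            for p in range(m + 1):
                if Mf[i][p] <= 0:
                    continue
                for q in range(p + sc.min_del_len, m + 1):
                    if Mr[n - i][m - q] <= 0:
                        continue
                    best = max(best, Mf[i][p] + Mr[n - i][m - q])
        else:  # running prefix max; same enumeration, tractable on 2-kb refs
            pre, run = [], -(10**9)
            for p in range(m + 1):
                run = max(run, Mf[i][p] if Mf[i][p] > 0 else -(10**9))
                pre.append(run)
            for q in range(sc.min_del_len, m + 1):
                if Mr[n - i][m - q] > 0 and pre[q - sc.min_del_len] > 0:
                    best = max(best, pre[q - sc.min_del_len] + Mr[n - i][m - q])
    if best <= 0:
        return -(10**9)
    return best + sc.long_del_penalty


def oracle_best_score(
    read: str, ref: str, sc: fd.Scoring, allow_long_deletion: bool, exhaustive: bool = True
) -> int:
    """Best over both strands and, optionally, the single-long-gap split."""
    from founderdel.locus import revcomp

    best = -(10**9)
    for oriented in (read, revcomp(read)):
        contig, _ = oracle_local_score(oriented, ref, sc)
        best = max(best, contig)
        if allow_long_deletion:
            best = max(best, oracle_split_score(oriented, ref, sc, exhaustive))
    return best


def random_mini_locus(rng: np.random.Generator, ref_len: int, del_len: int, hom: int):
    """A small reference with a deletion whose junction has ``hom`` bp of
    planted microhomology; returns (ref_seq, alt_seq, del_start)."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=ref_len)
    s = ref_len // 3
    e = s + del_len
    # plant homology: make ref[s:s+hom] == ref[e:e+hom], and break it on
    # both sides so the run length is exactly hom
    seq[e : e + hom] = seq[s : s + hom]
    seq[e + hom] = bases[(np.nonzero(bases == seq[s + hom])[0][0] + 1) % 4]
    seq[e - 1] = bases[(np.nonzero(bases == seq[s - 1])[0][0] + 1) % 4]
    ref_seq = "".join(seq)
    alt_seq = ref_seq[:s] + ref_seq[e:]
    return ref_seq, alt_seq, s
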