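"""Background-ancestry inference.

A 3-state HMM (BB = homozygous B6 background, BC = heterozygous,
CC = homozygous CAST) assigns a background state to every SNP of a
sample, by forward-backward posterior decoding.  Crossovers appear as
state changes between successive SNPs; genotypes conflicting with their
background are candidate gene conversions (or sequencing errors).

Emissions: the concordant call has probability 1 - eps, the two
discordant calls share eps; missing calls are uninformative.
Transitions over a physical gap of d bp: state i stays with probability
e^{-r d}; otherwise it jumps according to a matrix T with direct
BB <-> CC moves disallowed (those must pass through BC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the sequential forward-backward scan
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


STATES = ("BB", "BC", "CC")
# jump matrix: BB and CC can only move to BC; BC splits evenly
_T = np.array(
    [
        [0.0, 1.0, 0.0],
        [0.5, 0.0, 0.5],
        [0.0, 1.0, 0.0],
    ]
)


@dataclass
class HmmParams:
    """Free parameters of the background HMM.

    genotyping_error : emission error probability eps in (0, 0.5)
    switch_rate : per-bp background switch rate r > 0
    posterior_threshold : per-SNP posterior below which the assignment is
        counted as low-confidence (segments record their mean posterior)
    """

    genotyping_error: float = 0.002
    switch_rate: float = 1e-7
    posterior_threshold: float = 0.9

    def __post_init__(self):
        if not 0.0 < self.genotyping_error < 0.5:
            raise ValueError("genotyping_error must be in (0, 0.5)")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")
        if not 0.5 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must be in (0.5, 1]")


@dataclass
class BackgroundSegment:
    """A maximal run of SNPs sharing one decoded background state."""

    sample_id: str
    chrom: str
    start_idx: int  # first SNP index (inclusive)
    end_idx: int  # last SNP index (inclusive)
    state: str  # 'BB' | 'BC' | 'CC'
    mean_posterior: float
    start_pos: int
    end_pos: int

    @property
    def n_snps(self) -> int:
        return self.end_idx - self.start_idx + 1


def emission_matrix(calls: np.ndarray, eps: float) -> np.ndarray:
    """(n, 3) emission likelihoods for coded calls (-1/0/1/2)."""
    n = len(calls)
    e = np.full((n, 3), eps / 2.0)
    for state, call in enumerate((0, 1, 2)):  # concordant call per state
        e[calls == call, state] = 1.0 - eps
    e[calls == -1, :] = 1.0  # missing: uninformative
    return e


@njit
def _forward_backward(emis, stay, T):  # pragma: no cover - numba kernel
    n = emis.shape[0]
    k = emis.shape[1]
    alpha = np.empty((n, k))
    beta = np.empty((n, k))
    scale = np.empty(n)
    for j in range(k):
        alpha[0, j] = emis[0, j] / k
    s = alpha[0].sum()
    scale[0] = s
    for j in range(k):
        alpha[0, j] /= s
    for t in range(1, n):
        p = stay[t - 1]
        for j in range(k):
            acc = 0.0
            for i in range(k):
                trans = p if i == j else (1.0 - p) * T[i, j]
                acc += alpha[t - 1, i] * trans
            alpha[t, j] = acc * emis[t, j]
        s = alpha[t].sum()
        scale[t] = s
        for j in range(k):
            alpha[t, j] /= s
    for j in range(k):
        beta[n - 1, j] = 1.0
    for t in range(n - 2, -1, -1):
        p = stay[t]
        for i in range(k):
            acc = 0.0
            for j in range(k):
                trans = p if i == j else (1.0 - p) * T[i, j]
                acc += trans * emis[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / scale[t + 1]
    post = alpha * beta
    for t in range(n):
        s = post[t].sum()
        for j in range(k):
            post[t, j] /= s
    loglik = np.log(scale).sum()
    return post, loglik


def forward_backward(
    calls: np.ndarray, positions: np.ndarray, params: HmmParams
):
    """Posterior state probabilities per SNP and the data log-likelihood.

    ``calls`` is the coded genotype vector (-1 missing, 0 homB6, 1 het,
    2 homCAST); ``positions`` the matching bp positions.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.float64)
    if len(calls) != len(positions):
        raise ValueError("calls and positions must have equal length")
    if len(positions) > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if len(calls) == 0:
        return np.zeros((0, 3)), 0.0
    emis = emission_matrix(calls, params.genotyping_error)
    gaps = np.diff(positions)
    stay = np.exp(-params.switch_rate * gaps)
    return _forward_backward(emis, stay, _T)


def infer_background(
    genotypes, snp_map, params: HmmParams | None = None
) -> list:
    """Decode background segments for one sample across all chromosomes.

    Returns a list of :class:`BackgroundSegment`; per-SNP state is the
    posterior argmax.  A fully missing chromosome yields no segments and
    a warning.
    """
    if params is None:
        params = HmmParams()
    segments = []
    for chrom in snp_map.chroms:
        calls = genotypes.calls[chrom]
        pos = snp_map.pos[chrom]
        if len(calls) == 0:
            continue
        if np.all(calls == -1):
            warnings.warn(
                f"all calls missing on {chrom} for {genotypes.sample_id}; "
                "background unassigned"
            )
            continue
        post, _ = forward_backward(calls, pos, params)
        states = np.argmax(post, axis=1)
        maxpost = post[np.arange(len(states)), states]
        # run-length encode
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change - 1, [len(states) - 1]])
        for s, e in zip(starts, ends):
            segments.append(
                BackgroundSegment(
                    genotypes.sample_id,
                    chrom,
                    int(s),
                    int(e),
                    STATES[states[s]],
                    float(maxpost[s : e + 1].mean()),
                    int(pos[s]),
                    int(pos[e]),
                )
            )
    return segments


def states_per_snp(segments, snp_map) -> dict:
    """chrom -> int8 array of decoded states (-1 where unassigned)."""
    out = {
        c: np.full(snp_map.n_sites(c), -1, dtype=np.int8) for c in snp_map.chroms
    }
    for seg in segments:
        out[seg.chrom][seg.start_idx : seg.end_idx + 1] = STATES.index(seg.state)
    return out
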