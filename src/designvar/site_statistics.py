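"""Per-site entropy and Kullback-Leibler divergence between alignment profiles.

Site variability is measured as Shannon entropy H_i = -sum_j p_ij ln p_ij
(natural log, nats) of the amino-acid frequency distribution in column i.
Divergence between a focal alignment (typically designed sequences) and a
reference alignment (natural sequences) is the per-site KL divergence
D_i = sum_j p_ij ln(p_ij / q_ij). Frequencies entering a KL computation are
pseudocounted: 1/20 is added to each of the 20 residue counts before
normalising, so every frequency is strictly positive. A rank-ordered variant
sorts both 20-vectors by descending frequency and compares frequencies at
equal rank, measuring distribution *shape* irrespective of residue identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msa_io import Alignment, CountMatrix, SiteMap, build_site_map, column_counts

LN20 = float(np.log(20.0))


@dataclass
class FrequencyProfile:
    """L x 20 per-site amino-acid frequencies; rows sum to 1."""

    freqs: np.ndarray
    pseudocounted: bool
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 20:
            raise ValueError("freqs must be L x 20")
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if not np.allclose(self.freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each frequency row must sum to 1")
        if self.pseudocounted and not (self.freqs > 0).all():
            raise ValueError("pseudocounted profile must be strictly positive")

    @property
    def n_sites(self) -> int:
        return self.freqs.shape[0]


@dataclass
class EntropyVector:
    """Per-site Shannon entropy in nats; each value in [0, ln 20]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < -1e-9) | (self.values > LN20 + 1e-9)).any():
            raise ValueError("entropies must lie in [0, ln 20]")


@dataclass
class DivergenceVector:
    """Per-site KL divergence in nats; mode 'standard' or 'rank_ordered'."""

    values: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("standard", "rank_ordered"):
            raise ValueError(f"unknown divergence mode {self.mode!r}")
        if (self.values < -1e-12).any():
            raise ValueError("KL divergence must be nonnegative")


def site_frequencies(counts: CountMatrix, pseudocount: bool = False) -> FrequencyProfile:
    """Normalise per-site counts to frequencies.

    With ``pseudocount=True`` each of the 20 counts is incremented by 1/20
    before normalising (row denominator ``site_total + 1``); this guarantees
    strictly positive frequencies and is required for KL computations.
    """
    if (counts.site_totals == 0).any():
        raise ValueError("cannot compute frequencies for a site with zero counts")
    c = counts.counts.astype(float)
    if pseudocount:
        c = c + 1.0 / 20.0
    freqs = c / c.sum(axis=1, keepdims=True)
    return FrequencyProfile(freqs, pseudocounted=pseudocount, positions=counts.positions)


def site_entropy(profile: FrequencyProfile) -> EntropyVector:
    """Shannon entropy per site, H_i = -sum_j p_ij ln p_ij, with 0 ln 0 := 0."""
    p = profile.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return EntropyVector(-terms.sum(axis=1))


def mean_entropy(entropy: EntropyVector) -> float:
    """Arithmetic mean entropy over sites — the alignment-level variability."""
    if entropy.values.size == 0:
        raise ValueError("empty entropy vector")
    return float(entropy.values.mean())


def kl_divergence(p: FrequencyProfile, q: FrequencyProfile) -> DivergenceVector:
    """Per-site KL divergence of focal profile p from reference profile q."""
    _check_kl_inputs(p, q)
    pf, qf = p.freqs, q.freqs
    values = np.where(pf > 0, pf * (np.log(pf) - np.log(qf)), 0.0).sum(axis=1)
    return DivergenceVector(np.maximum(values, 0.0), mode="standard")


def rank_ordered_kl(p: FrequencyProfile, q: FrequencyProfile) -> DivergenceVector:
    """KL divergence of frequency *ranks*: both per-site 20-vectors are sorted
    in descending order and compared at equal rank, so the result depends only
    on distribution shape, not on which residues carry the mass."""
    _check_kl_inputs(p, q)
    pf = -np.sort(-p.freqs, axis=1)
    qf = -np.sort(-q.freqs, axis=1)
    values = np.where(pf > 0, pf * (np.log(pf) - np.log(qf)), 0.0).sum(axis=1)
    return DivergenceVector(np.maximum(values, 0.0), mode="rank_ordered")


def per_protein_mean(div: DivergenceVector) -> float:
    """Mean of per-site divergences — the protein-level similarity score."""
    if div.values.size == 0:
        raise ValueError("empty divergence vector")
    return float(div.values.mean())


def _check_kl_inputs(p: FrequencyProfile, q: FrequencyProfile) -> None:
    if p.freqs.shape != q.freqs.shape:
        raise ValueError("profiles must cover the same sites")
    if (q.freqs <= 0).any():
        raise ValueError(
            "reference profile contains zero frequencies; apply the pseudocount"
        )


def split_half_control(
    natural: Alignment,
    site_map: SiteMap | None = None,
    seed: int = 0,
    mode: str = "standard",
) -> float:
    """Natural-vs-natural baseline: mean KL of one random half of the natural
    alignment against the other half.

    The records are partitioned uniformly at random (without replacement) into
    halves of sizes floor(n/2) and ceil(n/2); the smaller half is the focal
    set, the larger the reference. Both halves are pseudocounted. Deterministic
    given ``seed``.
    """
    if natural.n_records < 4:
        raise ValueError("split-half control needs at least 4 records")
    if site_map is None:
        site_map = build_site_map(natural)
    rng = np.random.default_rng(seed)
    n = natural.n_records
    perm = rng.permutation(n)
    half_a_idx = set(perm[: n // 2].tolist())

    seqs_a = [natural.records[i][1] for i in range(n) if i in half_a_idx]
    seqs_b = [natural.records[i][1] for i in range(n) if i not in half_a_idx]

    from .msa_io import DEFAULT_ALPHABET

    idx = {aa: j for j, aa in enumerate(DEFAULT_ALPHABET.letters)}

    def half_counts(seqs: list[str]) -> np.ndarray:
        rows = np.zeros((len(site_map), 20), dtype=np.int64)
        for i, (col, _pos) in enumerate(site_map.pairs):
            for s in seqs:
                j = idx.get(s[col])
                if j is not None:
                    rows[i, j] += 1
        return rows

    counts_a, counts_b = half_counts(seqs_a), half_counts(seqs_b)
    # a site is usable only if both halves observed at least one residue there
    keep = (counts_a.sum(axis=1) > 0) & (counts_b.sum(axis=1) > 0)
    if not keep.any():
        raise ValueError("no site has countable residues in both halves")
    positions = np.asarray(site_map.positions)[keep]

    def to_profile(rows: np.ndarray) -> FrequencyProfile:
        cm = CountMatrix(rows[keep], rows[keep].sum(axis=1), positions)
        return site_frequencies(cm, pseudocount=True)

    p, q = to_profile(counts_a), to_profile(counts_b)
    div = kl_divergence(p, q) if mode == "standard" else rank_ordered_kl(p, q)
    return per_protein_mean(div)
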