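"""Pairwise difference counts and Tamura–Nei (TN93) distances.

Missing data (``-`` and ``N``) are handled by *pairwise deletion*: each pair
of sequences is compared only at sites where both carry an unambiguous base.
The TN93 correction separates purine transitions, pyrimidine transitions and
transversions, with base frequencies estimated once from the pooled
alignment (per-pair estimation is available as an option).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import Alignment, MISSING_CODES


@dataclass
class DistanceMatrix:
    """A symmetric labelled distance matrix tagged with its metric.

    ``metric`` is one of ``diff_count``, ``tn93``, ``fst``, ``net_pairwise``.
    The diagonal is zero; ``diff_count``/``tn93`` entries are non-negative,
    while ``fst``/``net_pairwise`` may be slightly negative.
    """

    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise InputError("distance matrix is not symmetric")

    def __getitem__(self, pair) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              self.metric)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, metric: str) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(l) for l in df.index], df.to_numpy(float), metric)


def _comparable_mask(enc: np.ndarray) -> np.ndarray:
    """Boolean (n, L) mask of unambiguous bases."""
    mask = np.ones(enc.shape, dtype=bool)
    for code in MISSING_CODES:
        mask &= enc != code
    return mask


def pairwise_diff_matrix(aln: Alignment, strict: bool = False) -> DistanceMatrix:
    """Count differing sites for every sequence pair (pairwise deletion).

    A pair with zero comparable sites gets NaN and a warning, or raises
    :class:`InputError` when ``strict``. The matrix carries the per-pair
    comparable-site counts as ``matrix.comparable_sites``.
    """
    if len(aln) < 2:
        raise InputError("need at least two sequences")
    enc = aln.encoded()
    ok = _comparable_mask(enc)
    n = len(aln)
    diffs = np.zeros((n, n))
    comparable = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        neq = (enc[i] != enc[i + 1:]) & both
        diffs[i, i + 1:] = neq.sum(axis=1)
        comparable[i, i + 1:] = both.sum(axis=1)
    diffs += diffs.T
    comparable += comparable.T
    np.fill_diagonal(comparable, aln.length)
    empty = (comparable == 0) & ~np.eye(n, dtype=bool)
    if empty.any():
        if strict:
            i, j = np.argwhere(empty)[0]
            raise InputError(
                f"no comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
        warnings.warn("some pairs share no comparable sites; distances set to NaN")
        diffs[empty] = np.nan
    dm = DistanceMatrix(list(aln.ids), diffs, "diff_count")
    dm.comparable_sites = comparable
    return dm


def base_frequencies(aln: Alignment) -> np.ndarray:
    """Frequencies of A, C, G, T pooled over all sequences (missing excluded)."""
    enc = aln.encoded()
    counts = np.array([(enc == b).sum() for b in range(4)], dtype=float)
    total = counts.sum()
    if total == 0:
        raise InputError("alignment contains no unambiguous bases")
    return counts / total


def _tn93_pair(enc_i, enc_j, freqs, strict):
    """TN93 distance for one encoded pair; NaN on saturation unless strict."""
    ok = np.ones(enc_i.shape, bool)
    for code in MISSING_CODES:
        ok &= (enc_i != code) & (enc_j != code)
    n_sites = int(ok.sum())
    if n_sites == 0:
        if strict:
            raise InputError("no comparable sites for a pair")
        return np.nan
    a, b = enc_i[ok], enc_j[ok]
    neq = a != b
    # A=0 C=1 G=2 T=3; purines {0,2}, pyrimidines {1,3}
    purine = lambda x: (x == 0) | (x == 2)
    p1 = float((neq & purine(a) & purine(b)).sum()) / n_sites      # A<->G
    p2 = float((neq & ~purine(a) & ~purine(b)).sum()) / n_sites    # C<->T
    q = float((neq & (purine(a) ^ purine(b))).sum()) / n_sites     # transversions

    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gR)
    w2 = 1.0 - p2 / k2 - q / (2.0 * gY)
    w3 = 1.0 - q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        if strict:
            raise InputError("TN93 saturation: logarithm argument <= 0")
        warnings.warn("TN93 saturation for a pair; distance set to NaN")
        return np.nan
    return -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)


def tn93_distance_matrix(aln: Alignment, strict: bool = False,
                         per_pair_freqs: bool = False) -> DistanceMatrix:
    """Tamura–Nei (1993) distance matrix with pairwise deletion.

    Base frequencies come from the pooled alignment by default; with
    ``per_pair_freqs`` they are re-estimated from each pair's comparable
    sites. Saturated pairs (log argument <= 0) are NaN with a warning, or an
    error in strict mode.
    """
    if len(aln) < 2:
        raise InputError("need at least two sequences")
    enc = aln.encoded()
    pooled = base_frequencies(aln)
    if (pooled == 0).any() and not per_pair_freqs:
        raise InputError("TN93 requires all four base frequencies > 0")
    n = len(aln)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if per_pair_freqs:
                pair = Alignment([aln.ids[i], aln.ids[j]],
                                 [aln.sequences[i], aln.sequences[j]])
                freqs = base_frequencies(pair)
                if (freqs == 0).any():
                    freqs = pooled
            else:
                freqs = pooled
            out[i, j] = out[j, i] = _tn93_pair(enc[i], enc[j], freqs, strict)
    return DistanceMatrix(list(aln.ids), out, "tn93")


@dataclass
class CladeDistanceSummary:
    """Within/between/net mean pairwise distances aggregated by clade.

    ``within`` maps clade -> mean over its internal pairs (NaN for singleton
    clades); ``between`` and ``net`` are symmetric DataFrames over clades,
    with ``net(i, j) = between(i, j) - (within_i + within_j) / 2``. The
    headline means/sds aggregate over the clades (within) and the unordered
    clade pairs (between).
    """

    clades: list[str]
    n_members: pd.Series
    within: pd.Series
    between: pd.DataFrame
    net: pd.DataFrame
    within_mean: float
    within_sd: float
    between_mean: float
    between_sd: float

    @property
    def ratio(self) -> float:
        """Between-clade mean divided by within-clade mean."""
        return self.between_mean / self.within_mean


def clade_distance_summary(d: DistanceMatrix,
                           partition: dict[str, str]) -> CladeDistanceSummary:
    """Summarise a haplotype distance matrix by a clade partition."""
    missing = [l for l in d.labels if l not in partition]
    if missing:
        raise InputError(f"labels not assigned to a clade: {missing}")
    clades = sorted(set(partition.values()))
    members = {c: [l for l in d.labels if partition[l] == c] for c in clades}
    for c in clades:
        if not members[c]:
            raise InputError(f"clade {c!r} has no members")
    idx = {l: k for k, l in enumerate(d.labels)}

    within = {}
    for c in clades:
        m = members[c]
        if len(m) < 2:
            within[c] = np.nan
            continue
        vals = [d.values[idx[a], idx[b]]
                for i, a in enumerate(m) for b in m[i + 1:]]
        within[c] = float(np.mean(vals))
    within = pd.Series(within)

    between = pd.DataFrame(0.0, index=clades, columns=clades)
    for i, ci in enumerate(clades):
        for cj in clades[i + 1:]:
            vals = [d.values[idx[a], idx[b]] for a in members[ci]
                    for b in members[cj]]
            between.loc[ci, cj] = between.loc[cj, ci] = float(np.mean(vals))
    np.fill_diagonal(between.values, np.nan)

    net = between.copy()
    for i, ci in enumerate(clades):
        for cj in clades[i + 1:]:
            corr = between.loc[ci, cj] - (within[ci] + within[cj]) / 2.0
            net.loc[ci, cj] = net.loc[cj, ci] = corr

    pair_vals = np.array([between.loc[ci, cj] for i, ci in enumerate(clades)
                          for cj in clades[i + 1:]])
    w = within.dropna().to_numpy()
    n_members = pd.Series({c: len(members[c]) for c in clades})
    return CladeDistanceSummary(
        clades, n_members, within, between, net,
        within_mean=float(w.mean()) if w.size else np.nan,
        within_sd=float(w.std(ddof=1)) if w.size > 1 else np.nan,
        between_mean=float(pair_vals.mean()) if pair_vals.size else np.nan,
        between_sd=float(pair_vals.std(ddof=1)) if pair_vals.size > 1 else np.nan,
    )
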