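"""Within-population diversity, distance-based F_ST (Phi_ST), AMOVA, and
net population distances.

All statistics operate on the haplotype count matrix plus an inter-haplotype
distance matrix. Following the haplotype-data convention of the classic
population-genetics software, the raw number of pairwise differences between
haplotypes is used directly as the squared Euclidean distance entering the
AMOVA sum-of-squares decomposition; F_ST here is therefore the two-stratum
AMOVA Phi-statistic. Variance (sd) estimators for diversity indices follow
Nei (1987) / Tajima as implemented by that software's manual formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .errors import InputError, InsufficientDataError
from .io import Alignment, HaplotypeTable, MISSING_CODES


def _align_counts(table: HaplotypeTable, d: DistanceMatrix) -> np.ndarray:
    if list(table.ids) != list(d.labels):
        try:
            d = d.submatrix(list(table.ids))
        except (ValueError, InputError) as exc:
            raise InputError("distance labels do not cover haplotype table") \
                from exc
    return np.asarray(d.values, float)


# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityEstimates:
    """Per-population diversity indices."""

    population: str
    n: int                   # samples
    k: int                   # distinct haplotypes
    S: int | None            # polymorphic sites (None when no alignment given)
    h: float                 # haplotype (gene) diversity, with n/(n-1) factor
    h_sd: float
    pi_count: float          # mean number of pairwise differences (Pi)
    pi_count_sd: float
    pi_site: float           # nucleotide diversity (pi = Pi / L)
    pi_site_sd: float


def diversity(table: HaplotypeTable, population: str, d: DistanceMatrix,
              L: int, S: int | None = None) -> DiversityEstimates:
    """Haplotype diversity, mean pairwise differences and nucleotide diversity.

    h uses Nei's unbiased estimator ``n/(n-1) * (1 - sum p_i^2)`` with his
    sampling variance; Pi is the mean distance over the ``n(n-1)/2`` sample
    pairs; pi = Pi / L with the standard total variance, and
    sd(Pi) = sd(pi) * L.
    """
    if population not in table.populations:
        raise InputError(f"unknown population {population!r}")
    c = table.counts[population].to_numpy(float)
    n = int(c.sum())
    if n < 2:
        raise InsufficientDataError(
            f"population {population!r} has {n} sample(s); need >= 2")
    D = _align_counts(table, d)
    p = c / n
    sum2 = float((p ** 2).sum())
    sum3 = float((p ** 3).sum())
    h = n / (n - 1.0) * (1.0 - sum2)
    var_h = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    h_sd = float(np.sqrt(max(var_h, 0.0)))

    # Pi: sum over ordered sample pairs c_i c_j d_ij (i != j) / (n(n-1))
    pi_count = float(c @ D @ c) / (n * (n - 1.0))
    pi_site = pi_count / L
    var_pi_site = ((n + 1.0) / (3.0 * (n - 1.0) * L)) * pi_site \
        + (2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0))) * pi_site ** 2
    pi_site_sd = float(np.sqrt(max(var_pi_site, 0.0)))
    return DiversityEstimates(
        population=population, n=n, k=int((c > 0).sum()), S=S,
        h=float(h), h_sd=h_sd,
        pi_count=pi_count, pi_count_sd=pi_site_sd * L,
        pi_site=pi_site, pi_site_sd=pi_site_sd,
    )


def polymorphic_sites(aln: Alignment, haplotype_ids: list[str]) -> int:
    """Number of sites with >= 2 distinct unambiguous bases among the
    given haplotypes."""
    if not haplotype_ids:
        raise InputError("no haplotypes given")
    enc = aln.subset(list(haplotype_ids)).encoded()
    ok = np.ones(enc.shape, bool)
    for code in MISSING_CODES:
        ok &= enc != code
    S = 0
    for col, colok in zip(enc.T, ok.T):
        bases = set(col[colok].tolist())
        if len(bases) >= 2:
            S += 1
    return int(S)


def diversity_table(table: HaplotypeTable, d: DistanceMatrix, L: int,
                    aln: Alignment | None = None) -> pd.DataFrame:
    """Diversity summary across all populations with n >= 2."""
    rows = []
    for pop in table.populations:
        c = table.counts[pop]
        if int(c.sum()) < 2:
            continue
        S = None
        if aln is not None:
            present = [h for h in table.ids if c[h] > 0]
            S = polymorphic_sites(aln, present)
        est = diversity(table, pop, d, L, S=S)
        rows.append(est.__dict__)
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# AMOVA and F_ST


@dataclass
class AmovaResult:
    """One-level AMOVA decomposition (Excoffier-style, squared distances)."""

    strata: list[str]
    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    ssd_total: float
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    n: int
    p_value: float | None = None
    n_permutations: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within],
                "SSD": [self.ssd_among, self.ssd_within],
                "variance_component": [self.sigma2_among, self.sigma2_within],
                "percent_variation": [self.percent_among, self.percent_within],
            },
            index=["among", "within"],
        )


def _amova_from_group_counts(G: np.ndarray, D2: np.ndarray):
    """Core decomposition; G is (n_strata, n_haplotypes) integer counts and
    D2 the squared-distance matrix between haplotypes."""
    sizes = G.sum(axis=1)
    N = float(sizes.sum())
    P = G.shape[0]
    total_counts = G.sum(axis=0)
    ssd_total = float(total_counts @ D2 @ total_counts) / (2.0 * N)
    ssd_within = float(sum(
        (G[g] @ D2 @ G[g]) / (2.0 * sizes[g]) for g in range(P) if sizes[g] > 0
    ))
    ssd_among = ssd_total - ssd_within
    df_among = P - 1
    df_within = int(N) - P
    if df_within <= 0:
        raise InsufficientDataError("no within-stratum degrees of freedom")
    sigma2_w = ssd_within / df_within
    n_bar = (N - float((sizes ** 2).sum()) / N) / df_among
    ms_a = ssd_among / df_among
    sigma2_a = (ms_a - sigma2_w) / n_bar
    total = sigma2_a + sigma2_w
    phi = sigma2_a / total if total != 0 else 0.0
    return (ssd_total, ssd_within, ssd_among, df_among, df_within,
            sigma2_a, sigma2_w, phi)


def amova(table: HaplotypeTable, d: DistanceMatrix,
          grouping: dict[str, str] | None = None,
          n_permutations: int | None = None,
          seed: int | None = None) -> AmovaResult:
    """One-level AMOVA over populations, or over strata pooling populations.

    ``grouping`` maps population -> stratum; by default every population is
    its own stratum. With ``n_permutations`` an individual-level permutation
    p-value for Phi_ST is computed.
    """
    D2 = _align_counts(table, d)
    pops = table.populations
    if grouping is None:
        grouping = {p: p for p in pops}
    missing = [p for p in pops if p not in grouping]
    if missing:
        raise InputError(f"populations without stratum: {missing}")
    strata = sorted(set(grouping.values()))
    if len(strata) < 2:
        raise InputError("AMOVA needs at least two strata")
    G = np.zeros((len(strata), len(table.ids)))
    for p in pops:
        G[strata.index(grouping[p])] += table.counts[p].to_numpy(float)

    (ssd_t, ssd_w, ssd_a, df_a, df_w,
     s2a, s2w, phi) = _amova_from_group_counts(G, D2)
    total = s2a + s2w
    result = AmovaResult(
        strata=strata, df_among=df_a, df_within=df_w,
        ssd_among=ssd_a, ssd_within=ssd_w, ssd_total=ssd_t,
        sigma2_among=s2a, sigma2_within=s2w,
        percent_among=100.0 * s2a / total, percent_within=100.0 * s2w / total,
        phi_st=phi, n=int(G.sum()),
    )
    if n_permutations:
        rng = np.random.default_rng(seed)
        hap_idx = np.repeat(np.arange(len(table.ids)),
                            G.sum(axis=0).astype(int))
        sizes = G.sum(axis=1).astype(int)
        count_ge = 0
        for _ in range(n_permutations):
            perm = rng.permutation(hap_idx)
            Gp = np.zeros_like(G)
            start = 0
            for g, size in enumerate(sizes):
                Gp[g] = np.bincount(perm[start:start + size],
                                    minlength=len(table.ids))
                start += size
            phi_p = _amova_from_group_counts(Gp, D2)[-1]
            if phi_p >= phi - 1e-12:
                count_ge += 1
        result.p_value = (count_ge + 1.0) / (n_permutations + 1.0)
        result.n_permutations = n_permutations
    return result


@dataclass
class FstResult:
    """Pairwise distance-based F_ST (Phi_ST) with permutation p-values."""

    fst: DistanceMatrix
    p_values: pd.DataFrame
    n_permutations: int
    seed: int | None

    def lower_upper_table(self) -> pd.DataFrame:
        """F_ST below the diagonal, permutation p-values above."""
        pops = self.fst.labels
        out = pd.DataFrame(np.nan, index=pops, columns=pops)
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    out.loc[a, b] = self.fst.values[i, j]
                elif i < j:
                    out.loc[a, b] = self.p_values.loc[a, b]
        return out


def pairwise_fst(table: HaplotypeTable, d: DistanceMatrix,
                 n_perm: int = 1023, seed: int | None = None) -> FstResult:
    """Distance-based pairwise F_ST with a between-pair permutation test.

    For each population pair, individuals are shuffled between the two
    populations only; p = (#{permuted F_ST >= observed} + 1) / (n_perm + 1).
    Negative estimates are retained.
    """
    D2 = _align_counts(table, d)
    pops = [p for p in table.populations if table.counts[p].sum() >= 2]
    if len(pops) < 2:
        raise InsufficientDataError("need two populations with n >= 2")
    k = len(pops)
    fst = np.zeros((k, k))
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            ca = table.counts[pops[i]].to_numpy(float)
            cb = table.counts[pops[j]].to_numpy(float)
            G = np.vstack([ca, cb])
            phi = _amova_from_group_counts(G, D2)[-1]
            fst[i, j] = fst[j, i] = phi
            na = int(ca.sum())
            hap_idx = np.repeat(np.arange(len(table.ids)),
                                (ca + cb).astype(int))
            count_ge = 0
            for _ in range(n_perm):
                perm = rng.permutation(hap_idx)
                Ga = np.bincount(perm[:na], minlength=len(table.ids))
                Gb = np.bincount(perm[na:], minlength=len(table.ids))
                phi_p = _amova_from_group_counts(
                    np.vstack([Ga, Gb]).astype(float), D2)[-1]
                if phi_p >= phi - 1e-12:
                    count_ge += 1
            p = (count_ge + 1.0) / (n_perm + 1.0)
            pvals.loc[pops[i], pops[j]] = p
            pvals.loc[pops[j], pops[i]] = p
    return FstResult(DistanceMatrix(pops, fst, "fst"), pvals, n_perm, seed)


def net_population_distance(table: HaplotypeTable,
                            d: DistanceMatrix) -> DistanceMatrix:
    """Net (corrected) between-population mean pairwise differences.

    ``d_net(X, Y) = Pi_XY - (Pi_XX + Pi_YY) / 2`` with frequency-weighted
    averages throughout (within-population averages use the frequency form
    ``sum_i sum_j p_i p_j d_ij``, so identically composed populations are at
    distance exactly zero); slightly negative values are retained.
    """
    D = _align_counts(table, d)
    pops = [p for p in table.populations if table.counts[p].sum() >= 2]
    if len(pops) < 2:
        raise InsufficientDataError("need two populations with n >= 2")
    counts = {p: table.counts[p].to_numpy(float) for p in pops}
    sizes = {p: counts[p].sum() for p in pops}
    within = {
        p: float(counts[p] @ D @ counts[p]) / (sizes[p] * sizes[p])
        for p in pops
    }
    k = len(pops)
    net = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = pops[i], pops[j]
            between = float(counts[a] @ D @ counts[b]) / (sizes[a] * sizes[b])
            net[i, j] = net[j, i] = between - (within[a] + within[b]) / 2.0
    return DistanceMatrix(pops, net, "net_pairwise")
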