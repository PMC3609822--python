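"""Synthetic landscape-genetics data with known ground truth.

The generator emulates the structure of a basin-scale mtDNA survey: ~1.1-kb
haplotypes organised in deeply diverged clades, a handful of populations of
7–37 samples whose haplotype composition is locality-clustered, and a river
network that can (optionally) structure migration.

Model, in brief:

* Sequences: a random root; each clade ancestor adds ``Poisson(lambda_between)``
  substitutions at distinct sites; each haplotype adds
  ``Poisson(lambda_within)`` more. Substitutions pick a uniform different
  base, keeping expected pairwise differences analytic
  (between-clade ~ 2*lambda_between + 2*lambda_within,
  within-clade ~ 2*lambda_within).
* Geography: each clade is seeded at a "home" population; the effective
  distance between populations is ``d_eff = straight_km + beta * crossings``
  with ``beta`` the barrier strength in km per large-river crossing.
* Frequencies: population p's haplotype frequencies are drawn from a
  Dirichlet with mean proportional to ``exp(-d_eff(p, home(h)) / sigma)``
  and concentration ``kappa``; large kappa makes frequencies nearly
  deterministic functions of the landscape, so ``sigma -> inf`` with
  ``beta = 0`` approaches panmixia (all populations share one frequency
  vector) and small ``sigma`` yields locality-specific haplotypes.
* Samples: multinomial draws per population; sexes and jittered coordinates
  attached; files written in exactly the dialects the readers consume.

This is a phenomenological stand-in for coalescent migration models, chosen
for speed and closed-form tunability.

All randomness flows from one seed through named ``numpy`` SeedSequence
spawns, one stream per operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io import Alignment
from .rivers import River, RiverMap, straight_distance, tributary_crossings

_BASES = "ACGT"


@dataclass
class PopulationSpec:
    name: str
    latitude: float
    longitude: float
    n_samples: int
    cohort: str = ""


def default_populations() -> list[PopulationSpec]:
    """Seven populations with the survey's sample sizes on a basin-like map."""
    return [
        PopulationSpec("Malebo", -2.55, 16.42, 16, "west"),
        PopulationSpec("LacTumba", -0.85, 17.95, 7, "west"),
        PopulationSpec("Lomako", 0.89, 21.08, 35, "central"),
        PopulationSpec("Salonga", -2.10, 21.00, 7, "central"),
        PopulationSpec("Wamba", 0.01, 22.48, 37, "central"),
        PopulationSpec("Iyondji", -0.35, 22.80, 18, "central"),
        PopulationSpec("TL2", -2.50, 25.20, 16, "east"),
    ]


def default_rivers() -> RiverMap:
    """A stylised tributary network: three large rivers and one small.

    The north–south river separates the easternmost population from the
    rest; the east–west river runs between the two close central
    populations; headwaters terminate inside the map so detours exist.
    """
    return RiverMap([
        River("eastern_river", "large",
              [(24.1, 1.40), (24.25, -0.50), (24.40, -2.00),
               (24.55, -3.50), (24.65, -5.00)]),
        River("central_river", "large",
              [(20.80, -0.14), (21.80, -0.16), (22.60, -0.18),
               (23.40, -0.20)]),
        River("southern_river", "large",
              [(17.40, -2.95), (18.60, -3.05), (19.80, -3.10),
               (21.20, -3.20)]),
        River("minor_stream", "small",
              [(19.00, 0.50), (20.00, 0.30), (21.00, 0.10)]),
    ])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the survey being emulated: a 1121-site alignment, six
    clades totalling 54 haplotypes, seven populations with sizes
    16, 7, 35, 7, 37, 18, 16 (136 samples), and a river map whose barriers
    are genetically inert unless ``barrier_strength > 0``.
    """

    seed: int = 0
    L: int = 1121
    n_clades: int = 6
    haplotypes_per_clade: int = 9
    lambda_between: float = 14.0   # E[between-clade diffs] ~ 2(l_B + l_W) ~ 36
    lambda_within: float = 3.9     # E[within-clade diffs] ~ 2 l_W ~ 7.8
    populations: list[PopulationSpec] = field(default_factory=default_populations)
    rivers: RiverMap = field(default_factory=default_rivers)
    barrier_strength: float = 0.0   # beta, km of effective distance per crossing
    sigma_km: float = 80.0          # distance-decay scale of haplotype sharing
    kappa: float = 100.0            # Dirichlet concentration (higher = less noise)
    isolated_population: str | None = None  # pin one clade's home here
    # 0 = uniform substitution (analytic expectations); > 0 biases that
    # fraction of substitutions to transitions, for TN93-estimator tests
    transition_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_within < 0 or self.lambda_between <= self.lambda_within:
            raise InputError("need lambda_between > lambda_within >= 0")
        if self.barrier_strength < 0:
            raise InputError("barrier_strength must be >= 0")
        if self.lambda_between + self.lambda_within > self.L / 4:
            raise InputError("requested mutation counts too large for L")
        names = [p.name for p in self.populations]
        if len(names) != len(set(names)):
            raise InputError("duplicate population names")
        if self.isolated_population is not None \
                and self.isolated_population not in names:
            raise InputError(
                f"unknown isolated population {self.isolated_population!r}")


def identifiability_rivers() -> RiverMap:
    """A river layout that decorrelates the three geographic indices.

    Large rivers cut *short and medium* population pairs (the close central
    pair; the west-central corridor) and none walls off the far-eastern
    population, so detour inflation and crossing counts are not simply
    proxies for straight distance. Used by the isolation-by-distance
    recovery scenario, where the three predictors must be separable.
    """
    return RiverMap([
        River("central_river", "large",
              [(19.00, -0.10), (20.80, -0.14), (21.80, -0.16),
               (22.60, -0.18), (24.60, -0.22)]),
        River("western_river", "large",
              [(19.40, 2.00), (19.55, 0.00), (19.70, -2.60)]),
        River("eastern_stream", "small",
              [(24.10, 1.40), (24.40, -2.00), (24.65, -5.00)]),
    ])


def ibd_config(seed: int = 0) -> SimulationConfig:
    """Isolation-by-distance conditions: rivers present but inert (beta=0).

    Uses a moderate decay scale (F_ST still in its responsive range at the
    longest inter-population distances) and the decorrelated river layout,
    so straight distance is the identifiable driver.
    """
    return SimulationConfig(seed=seed, barrier_strength=0.0,
                            sigma_km=300.0,
                            rivers=identifiability_rivers())


def barrier_config(seed: int = 0, beta: float = 1000.0) -> SimulationConfig:
    """River-barrier conditions: each crossing adds ``beta`` km of
    effective distance at a moderate decay scale."""
    return SimulationConfig(seed=seed, barrier_strength=beta,
                            sigma_km=300.0)


def isolated_config(seed: int = 0, beta: float = 1500.0) -> SimulationConfig:
    """One population fully isolated behind a river, with its own clade."""
    return SimulationConfig(seed=seed, barrier_strength=beta,
                            isolated_population="TL2")


# ---------------------------------------------------------------------------


def _mutate(seq: np.ndarray, n_mut: int, rng,
            site_pool: np.ndarray | None = None,
            transition_bias: float = 0.0) -> np.ndarray:
    # encoding A=0 C=1 G=2 T=3: a shift of 2 is always the transition
    out = seq.copy()
    if n_mut == 0:
        return out
    pool = np.arange(seq.size) if site_pool is None else site_pool
    n_mut = min(n_mut, pool.size)
    sites = rng.choice(pool, size=n_mut, replace=False)
    if transition_bias > 0:
        is_ts = rng.random(n_mut) < transition_bias
        shifts = np.where(is_ts, 2, rng.choice([1, 3], size=n_mut))
    else:
        shifts = rng.integers(1, 4, size=n_mut)
    out[sites] = (out[sites] + shifts) % 4
    return out


def simulate_haplotypes(cfg: SimulationConfig,
                        rng=None) -> tuple[Alignment, dict[str, str]]:
    """Clade-structured haplotype sequences plus the true clade partition.

    Haplotype ids are ``T01, T02, ...`` grouped by clade ``A, B, C, ...``;
    all haplotypes are guaranteed distinct (colliding draws are re-mutated).
    Every clade draws all of its substitutions (stem and within-clade) from
    its own block of sites, disjoint from the other clades' blocks. Between
    two clades the distances are then exactly star-additive, so clade stems
    are the only groupings the site bootstrap can support — unopposed
    homoplasy between clades would otherwise let arbitrary clade pairs
    accrue spurious support.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    root = rng.integers(0, 4, size=cfg.L)
    site_order = rng.permutation(cfg.L)
    blocks = np.array_split(site_order, cfg.n_clades)
    ids: list[str] = []
    seqs: list[str] = []
    partition: dict[str, str] = {}
    seen: set[str] = set()
    hap_no = 0
    for c in range(cfg.n_clades):
        clade = chr(ord("A") + c)
        block = blocks[c]
        n_stem = min(int(rng.poisson(cfg.lambda_between)), block.size)
        stem_sites, within_pool = block[:n_stem], block[n_stem:]
        ancestor = _mutate(root, n_stem, rng, site_pool=stem_sites,
                           transition_bias=cfg.transition_bias)
        for _ in range(cfg.haplotypes_per_clade):
            hap_no += 1
            for _attempt in range(200):
                hap = _mutate(ancestor, rng.poisson(cfg.lambda_within), rng,
                              site_pool=within_pool,
                              transition_bias=cfg.transition_bias)
                s = "".join(_BASES[b] for b in hap)
                if s not in seen:
                    break
            else:
                raise InputError("could not generate distinct haplotypes; "
                                 "increase lambda_within or L")
            seen.add(s)
            hid = f"T{hap_no:02d}"
            ids.append(hid)
            seqs.append(s)
            partition[hid] = clade
    return Alignment(ids, seqs), partition


def effective_distances(cfg: SimulationConfig) -> pd.DataFrame:
    """Pairwise ``straight + beta * crossings`` km between populations."""
    pops = cfg.populations
    names = [p.name for p in pops]
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            d = straight_distance((a.latitude, a.longitude),
                                  (b.latitude, b.longitude))
            x = tributary_crossings((a.latitude, a.longitude),
                                    (b.latitude, b.longitude), cfg.rivers)
            v = d + cfg.barrier_strength * x
            out.loc[a.name, b.name] = out.loc[b.name, a.name] = v
    return out


def assign_clade_homes(cfg: SimulationConfig, rng) -> dict[str, str]:
    """Randomly seed each clade at a home population.

    With ``isolated_population`` set, exactly one clade is pinned there and
    the remaining clades are spread over the other populations.
    """
    names = [p.name for p in cfg.populations]
    clades = [chr(ord("A") + c) for c in range(cfg.n_clades)]
    homes: dict[str, str] = {}
    if cfg.isolated_population is not None:
        pinned = clades[-1]
        homes[pinned] = cfg.isolated_population
        others = [n for n in names if n != cfg.isolated_population]
        rest = clades[:-1]
        replace = len(rest) > len(others)
        chosen = rng.choice(others, size=len(rest), replace=replace)
        homes.update(dict(zip(rest, chosen)))
    else:
        replace = len(clades) > len(names)
        chosen = rng.choice(names, size=len(clades), replace=replace)
        homes.update(dict(zip(clades, chosen)))
    return homes


def simulate_population_frequencies(cfg: SimulationConfig,
                                    partition: dict[str, str],
                                    homes: dict[str, str],
                                    d_eff: pd.DataFrame,
                                    rng) -> pd.DataFrame:
    """Haplotype x population frequency matrix from the Dirichlet-decay model."""
    hap_ids = sorted(partition, key=lambda h: int(h[1:]))
    names = [p.name for p in cfg.populations]
    freqs = pd.DataFrame(0.0, index=hap_ids, columns=names)
    for pop in names:
        w = np.array([
            np.exp(-float(d_eff.loc[pop, homes[partition[h]]]) / cfg.sigma_km)
            for h in hap_ids
        ])
        w = np.maximum(w, 1e-12)
        alpha = cfg.kappa * w / w.sum()
        draw = rng.gamma(shape=np.maximum(alpha, 1e-8))
        if draw.sum() <= 0:
            draw = alpha
        freqs[pop] = draw / draw.sum()
    return freqs


@dataclass
class SyntheticDataset:
    """A complete synthetic study with its ground truth."""

    config: SimulationConfig
    alignment: Alignment            # per-sample sequences
    metadata: pd.DataFrame
    rivers: RiverMap
    haplotypes: Alignment           # distinct true haplotypes
    clades: dict[str, str]          # true haplotype -> clade
    homes: dict[str, str]           # clade -> home population
    frequencies: pd.DataFrame       # true haplotype x population frequencies
    d_eff: pd.DataFrame

    @property
    def cohorts(self) -> dict[str, str]:
        return {p.name: (p.cohort or p.name) for p in self.config.populations}

    def clade_of_sequence(self) -> dict[str, str]:
        """True clade keyed by sequence string (for mapping collapsed ids)."""
        return {seq: self.clades[hid]
                for hid, seq in zip(self.haplotypes.ids,
                                    self.haplotypes.sequences)}

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": outdir / "samples.fasta",
            "metadata": outdir / "metadata.tsv",
            "rivers": outdir / "rivers.geojson",
            "truth": outdir / "truth.json",
        }
        self.alignment.to_fasta(paths["alignment"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        self.rivers.to_geojson(paths["rivers"])
        truth = {
            "clades": self.clades,
            "homes": self.homes,
            "haplotype_sequences": dict(zip(self.haplotypes.ids,
                                            self.haplotypes.sequences)),
            "frequencies": self.frequencies.to_dict(),
            "d_eff": self.d_eff.to_dict(),
            "config": {
                k: v for k, v in asdict(self.config).items()
                if k not in ("populations", "rivers")
            },
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1)
        return paths


def simulate_samples(cfg: SimulationConfig,
                     outdir=None) -> SyntheticDataset:
    """Generate a full synthetic dataset (and optionally write its files)."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_hap, rng_home, rng_freq, rng_draw, rng_meta = (
        np.random.default_rng(s) for s in ss.spawn(5))

    haplotypes, partition = simulate_haplotypes(cfg, rng_hap)
    d_eff = effective_distances(cfg)
    homes = assign_clade_homes(cfg, rng_home)
    freqs = simulate_population_frequencies(cfg, partition, homes, d_eff,
                                            rng_freq)

    sample_ids: list[str] = []
    sample_seqs: list[str] = []
    meta_rows = []
    hap_seq = dict(zip(haplotypes.ids, haplotypes.sequences))
    import warnings as _warnings
    for pop in cfg.populations:
        if pop.n_samples == 0:
            _warnings.warn(f"population {pop.name!r} has 0 samples; excluded")
            continue
        p = freqs[pop.name].to_numpy()
        picks = rng_draw.choice(freqs.index.to_numpy(), size=pop.n_samples,
                                p=p / p.sum())
        for k, hid in enumerate(picks, start=1):
            sid = f"{pop.name}_{k:03d}"
            sample_ids.append(sid)
            sample_seqs.append(hap_seq[hid])
            meta_rows.append({
                "sample_id": sid,
                "population": pop.name,
                "sex": rng_meta.choice(["male", "female", "unknown"],
                                       p=[0.4, 0.4, 0.2]),
                "latitude": pop.latitude + rng_meta.normal(0, 0.12),
                "longitude": pop.longitude + rng_meta.normal(0, 0.12),
            })
    dataset = SyntheticDataset(
        config=cfg,
        alignment=Alignment(sample_ids, sample_seqs),
        metadata=pd.DataFrame(meta_rows),
        rivers=cfg.rivers,
        haplotypes=haplotypes,
        clades=partition,
        homes=homes,
        frequencies=freqs,
        d_eff=d_eff,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
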