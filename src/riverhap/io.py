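"""Reading aligned mtDNA sequences and sample metadata; haplotype collapsing.

The unit of analysis downstream is the *haplotype*: a distinct aligned
sequence. Samples carrying byte-identical sequences are collapsed into one
haplotype with per-population (and per-sex) counts. Identity is strict and
site-by-site, gaps included; ``N`` matches only itself, so two samples that
differ only at an ambiguous site are kept as distinct haplotypes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, ConsistencyError, InputError

ALPHABET = set("ACGTN-")

# integer encoding used for vectorised site comparisons
_CODE = {b: i for i, b in enumerate("ACGT")}
_CODE["-"] = 4
_CODE["N"] = 5
MISSING_CODES = (4, 5)  # gap and N are excluded by pairwise deletion

VALID_SEXES = {"male", "female", "unknown"}


@dataclass
class Alignment:
    """An aligned set of equal-length nucleotide sequences.

    Parameters
    ----------
    ids : list of str
        Unique sequence identifiers.
    sequences : list of str
        Upper-case strings over ``{A, C, G, T, -, N}``, all of equal length.
    """

    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise InputError("alignment is empty")
        if len(self.ids) != len(set(self.ids)):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dupes}")
        L = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {L}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise InputError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.ids)

    def encoded(self) -> np.ndarray:
        """Integer matrix (n, L); A..T = 0..3, gap = 4, N = 5."""
        return np.array(
            [[_CODE[b] for b in seq] for seq in self.sequences], dtype=np.int8
        )

    def subset(self, ids: list[str]) -> "Alignment":
        pos = {sid: k for k, sid in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise InputError(f"ids not in alignment: {missing}")
        return Alignment(list(ids), [self.sequences[pos[i]] for i in ids])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.ids, self.sequences):
                fh.write(f">{sid}\n{seq}\n")


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises
    ------
    InputError
        Empty file, duplicate ids, or characters outside ``ACGTN-``.
    AlignmentError
        Sequences of unequal length (the offending id is named).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return Alignment(ids, seqs)


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV.

    Expected columns: ``sample_id``, ``population``, and optionally ``sex``,
    ``latitude``, ``longitude``. The dialect is UTF-8, tab-separated, with
    ``#`` comment lines ignored. Missing sex becomes ``unknown``; missing
    coordinates are allowed and stay NaN.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str,
                                                         "population": str})
    required = {"sample_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"metadata missing required columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise InputError(f"duplicate sample_id values: {dupes}")
    if df["population"].isna().any() or (df["population"] == "").any():
        raise InputError("population labels must be non-empty")

    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown").replace("", "unknown")
    bad_sex = set(df["sex"]) - VALID_SEXES
    if bad_sex:
        raise InputError(f"invalid sex values: {sorted(bad_sex)}")

    for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="raise")
        vals = df[col].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise InputError(f"{col} outside [{lo}, {hi}]")
    return df.reset_index(drop=True)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population (and per-sex) sample counts.

    ``counts`` is a DataFrame indexed by haplotype id with one integer column
    per population; column sums equal per-population sample sizes.
    """

    ids: list[str]
    sequences: list[str]
    counts: pd.DataFrame
    sample_to_haplotype: dict[str, str] = field(default_factory=dict)
    sex_counts: pd.DataFrame | None = None  # MultiIndex (population, sex)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return int(self.counts.to_numpy().sum())

    def alignment(self) -> Alignment:
        """The haplotype representative sequences as an alignment."""
        return Alignment(list(self.ids), list(self.sequences))

    def population_counts(self, population: str) -> pd.Series:
        return self.counts[population]

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "sequence", pd.Series(self.sequences, index=self.ids))
        out.index.name = "haplotype_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", index_col="haplotype_id")
        df.index.name = None
        seqs = df.pop("sequence").tolist()
        counts = df.astype(int)
        return cls(list(df.index), seqs, counts)


def collapse_haplotypes(aln: Alignment, meta: pd.DataFrame) -> HaplotypeTable:
    """Collapse per-sample sequences into distinct haplotypes.

    Haplotype ids ``H001, H002, ...`` are assigned in order of first
    appearance in the alignment. Every alignment id must appear in the
    metadata's ``sample_id`` column.
    """
    pop_of = dict(zip(meta["sample_id"], meta["population"]))
    sex_of = dict(zip(meta["sample_id"], meta["sex"]))
    absent = [i for i in aln.ids if i not in pop_of]
    if absent:
        raise ConsistencyError(f"alignment ids absent from metadata: {absent}")

    seq_to_hap: dict[str, str] = {}
    ids: list[str] = []
    seqs: list[str] = []
    sample_to_hap: dict[str, str] = {}
    for sid, seq in zip(aln.ids, aln.sequences):
        hap = seq_to_hap.get(seq)
        if hap is None:
            hap = f"H{len(ids) + 1:03d}"
            seq_to_hap[seq] = hap
            ids.append(hap)
            seqs.append(seq)
        sample_to_hap[sid] = hap

    populations = sorted(set(pop_of[i] for i in aln.ids))
    counts = pd.DataFrame(0, index=ids, columns=populations, dtype=int)
    sexes = ["male", "female", "unknown"]
    sex_cols = pd.MultiIndex.from_product([populations, sexes],
                                          names=["population", "sex"])
    sex_counts = pd.DataFrame(0, index=ids, columns=sex_cols, dtype=int)
    for sid in aln.ids:
        hap, pop = sample_to_hap[sid], pop_of[sid]
        counts.loc[hap, pop] += 1
        sex_counts.loc[hap, (pop, sex_of[sid])] += 1
    return HaplotypeTable(ids, seqs, counts, sample_to_hap, sex_counts)


@dataclass
class LocalitySpecificity:
    """Haplotype sharing across populations (locality specificity)."""

    carriers: pd.Series           # haplotype -> number of carrying populations
    n_specific: int               # carried by exactly one population
    n_shared: int                 # carried by more than one
    shared_fraction_by_population: pd.Series  # shared/total among its haplotypes

    @property
    def proportion_specific(self) -> float:
        total = self.n_specific + self.n_shared
        return self.n_specific / total


def locality_specificity(table: HaplotypeTable) -> LocalitySpecificity:
    """Classify haplotypes as locality-specific vs shared among populations."""
    present = table.counts > 0
    carriers = present.sum(axis=1)
    n_specific = int((carriers == 1).sum())
    n_shared = int((carriers > 1).sum())
    shared_haps = carriers > 1
    frac = {}
    for pop in table.populations:
        haps_here = present[pop]
        total = int(haps_here.sum())
        shared_here = int((haps_here & shared_haps).sum())
        frac[pop] = shared_here / total if total else float("nan")
    return LocalitySpecificity(carriers, n_specific, n_shared, pd.Series(frac))
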