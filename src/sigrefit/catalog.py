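"""Build 96-context mutation catalogs from somatic SNVs and a reference genome.

The entry point for most analyses: a table of somatic single-nucleotide
variants (sample, chromosome, 1-based position, ref, alt) is looked up in an
indexed FASTA to recover the flanking bases, strand-collapsed to the 96
pyrimidine-referenced classes, and tallied into a samples x 96 matrix of
counts or fractions.  Counts may additionally be re-weighted by the
trinucleotide occurrence frequencies of the sequenced territory relative to
a target territory (e.g. exome capture vs. whole genome) before conversion
to fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .contexts import (
    BASES,
    CONTEXT_ORDER,
    CONTEXT_TRIPLETS,
    PYRIMIDINE_TRIPLETS,
    collapse_context,
    reverse_complement,
)

logger = logging.getLogger(__name__)

Mode = Literal["counts", "fractions"]


class CatalogError(ValueError):
    """Base class for catalog-construction failures."""


class ReferenceMismatchError(CatalogError):
    """Genome base at the mutation position differs from the stated ref allele."""


class AmbiguousBaseError(CatalogError):
    """A base in the trinucleotide context is not one of A/C/G/T."""


@dataclass(frozen=True)
class Mutation:
    """One somatic SNV.  Coordinates are 1-based and fully closed."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        ref = self.ref.upper()
        alt = self.alt.upper()
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)
        if ref not in BASES or alt not in BASES:
            raise CatalogError(f"not an SNV: {ref}>{alt} at {self.chrom}:{self.pos}")
        if ref == alt:
            raise CatalogError(f"ref equals alt at {self.chrom}:{self.pos}")
        if self.pos < 2:
            raise CatalogError(
                f"position {self.pos} too close to the chromosome start; "
                "both flanking bases must exist"
            )


@dataclass
class ContextMatrix:
    """Samples x 96 context profile matrix.

    ``df`` is indexed by sample id with columns in the canonical context
    order; ``mode`` records whether entries are raw counts or row-normalized
    fractions.
    """

    df: pd.DataFrame
    mode: Mode = "counts"

    def __post_init__(self) -> None:
        missing = [c for c in CONTEXT_ORDER if c not in self.df.columns]
        if missing:
            raise CatalogError(f"missing context columns: {missing[:3]}...")
        self.df = self.df.loc[:, list(CONTEXT_ORDER)].astype(float)
        self.df.index = self.df.index.astype(str).rename(None)
        if (self.df.to_numpy() < 0).any():
            raise CatalogError("negative entries in context matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def row(self, sample_id: str) -> np.ndarray:
        return self.df.loc[sample_id].to_numpy(dtype=float)

    def to_fractions(self) -> "ContextMatrix":
        """Row-normalize counts to fractions; all-zero rows stay zero with a warning."""
        if self.mode == "fractions":
            return self
        totals = self.df.sum(axis=1)
        zero = totals == 0
        if zero.any():
            logger.warning(
                "samples with zero mutations left as all-zero rows: %s",
                list(self.df.index[zero]),
            )
        safe = totals.replace(0, 1.0)
        return ContextMatrix(self.df.div(safe, axis=0), mode="fractions")


# ---------------------------------------------------------------------------
# context extraction

def _fetch_triplet(genome, chrom: str, pos: int) -> str:
    """Uppercased plus-strand triplet centered on 1-based ``pos`` (pyfaidx handle)."""
    if chrom not in genome:
        raise CatalogError(f"chromosome {chrom!r} not in genome")
    record = genome[chrom]
    if pos < 2 or pos > len(record) - 1:
        raise CatalogError(
            f"position {chrom}:{pos} lacks a flanking base in a chromosome of "
            f"length {len(record)}"
        )
    return str(record[pos - 2 : pos + 1]).upper()


def extract_context(m: Mutation, genome) -> str:
    """Canonical 96-class label for one mutation.

    ``genome`` is an indexed FASTA handle (``pyfaidx.Fasta``).  The genome
    base at the mutation position must equal the stated reference allele;
    ambiguous (non-ACGT) bases anywhere in the triplet are rejected.
    """
    triplet = _fetch_triplet(genome, m.chrom, m.pos)
    five, center, three = triplet[0], triplet[1], triplet[2]
    for b in (five, center, three, m.alt):
        if b not in BASES:
            raise AmbiguousBaseError(
                f"ambiguous base {b!r} in context of {m.chrom}:{m.pos}"
            )
    if center != m.ref:
        raise ReferenceMismatchError(
            f"genome has {center} at {m.chrom}:{m.pos}, mutation record says {m.ref}"
        )
    return collapse_context(five, m.ref, m.alt, three)


def build_context_matrix(
    muts: Iterable[Mutation], genome, mode: Mode = "counts"
) -> ContextMatrix:
    """Tally mutations per sample into the 96 context classes.

    Records whose context cannot be resolved (reference mismatch, ambiguous
    base, out-of-range position) are dropped with a per-sample logged count.
    A sample for which every record is dropped is an error.
    """
    muts = list(muts)
    if not muts:
        raise CatalogError("no mutations supplied")
    counts: dict[str, np.ndarray] = {}
    dropped: dict[str, int] = {}
    from .contexts import CONTEXT_INDEX

    for m in muts:
        row = counts.setdefault(m.sample_id, np.zeros(96))
        try:
            label = extract_context(m, genome)
        except CatalogError as exc:
            dropped[m.sample_id] = dropped.get(m.sample_id, 0) + 1
            logger.warning("dropping %s:%s in %s: %s", m.chrom, m.pos, m.sample_id, exc)
            continue
        row[CONTEXT_INDEX[label]] += 1
    for sample_id, n in dropped.items():
        logger.warning("sample %s: dropped %d unresolvable record(s)", sample_id, n)
        if counts[sample_id].sum() == 0:
            raise CatalogError(f"all records dropped for sample {sample_id}")
    df = pd.DataFrame.from_dict(counts, orient="index", columns=list(CONTEXT_ORDER))
    cm = ContextMatrix(df, mode="counts")
    return cm.to_fractions() if mode == "fractions" else cm


# ---------------------------------------------------------------------------
# territory normalization

def normalize_context_matrix(
    T: ContextMatrix, source: pd.Series, target: pd.Series
) -> ContextMatrix:
    """Re-weight context counts by trinucleotide territory frequencies.

    Each entry whose context has reference trinucleotide ``t`` is multiplied
    by ``target[t] / source[t]`` — converting counts observed in one genomic
    territory (e.g. exome capture) to the rates expected in another (e.g.
    whole genome) — and rows are then renormalized to fractions.
    """
    if T.mode != "counts":
        raise CatalogError("territory normalization applies to counts-mode matrices")
    source = validate_tri_counts(source)
    target = validate_tri_counts(target)
    ratio = np.array(
        [target[CONTEXT_TRIPLETS[c]] / source[CONTEXT_TRIPLETS[c]] for c in CONTEXT_ORDER]
    )
    scaled = T.df.mul(ratio, axis=1)
    return ContextMatrix(scaled, mode="counts").to_fractions()


def validate_tri_counts(counts: pd.Series) -> pd.Series:
    """Check a 32-triplet occurrence table: all keys present, all counts > 0."""
    counts = counts.astype(float)
    missing = [t for t in PYRIMIDINE_TRIPLETS if t not in counts.index]
    if missing:
        raise CatalogError(f"missing trinucleotides in count table: {missing}")
    counts = counts.loc[list(PYRIMIDINE_TRIPLETS)]
    if (counts <= 0).any():
        bad = list(counts.index[counts <= 0])
        raise CatalogError(f"non-positive trinucleotide counts for {bad}")
    return counts


def tri_counts_from_fasta(genome) -> pd.Series:
    """Count pyrimidine-centered trinucleotides over every position of a genome.

    Both strands are collapsed: a purine-centered triplet is counted as its
    reverse complement.  Triplets containing non-ACGT bases are skipped.
    """
    tally = {t: 0 for t in PYRIMIDINE_TRIPLETS}
    for name in genome.keys():
        seq = str(genome[name][:]).upper()
        for i in range(len(seq) - 2):
            tri = seq[i : i + 3]
            if any(b not in BASES for b in tri):
                continue
            if tri[1] not in "CT":
                tri = reverse_complement(tri)
            tally[tri] += 1
    return pd.Series(tally, name="count").loc[list(PYRIMIDINE_TRIPLETS)]


# ---------------------------------------------------------------------------
# file I/O

_TSV_COLUMNS = {"sample": "sample_id", "chr": "chrom", "pos": "pos",
                "ref": "ref", "alt": "alt"}


def read_mutations_tsv(path: str | Path) -> list[Mutation]:
    """Read a mutation table: TSV with header sample, chr, pos, ref, alt.

    Extra columns are ignored.  Non-SNV rows (multi-base or non-ACGT
    alleles) are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"mutation table missing columns {missing}")
    muts: list[Mutation] = []
    n_dropped = 0
    for rec in df.itertuples(index=False):
        ref = str(rec.ref).upper()
        alt = str(rec.alt).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES or ref == alt:
            n_dropped += 1
            continue
        muts.append(
            Mutation(str(rec.sample), str(rec.chr), int(rec.pos), ref, alt)
        )
    if n_dropped:
        logger.warning("%s: dropped %d non-SNV record(s)", path, n_dropped)
    if not muts:
        raise CatalogError(f"no SNV records in {path}")
    return muts


def read_mutations_vcf(path: str | Path, sample_id: str | None = None) -> list[Mutation]:
    """Read SNVs from a single-sample VCF.

    The sample id defaults to the file stem.  Multi-allelic rows are split
    into one record per alternate allele; non-SNV alleles are dropped with a
    warning.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".vcf")
    muts: list[Mutation] = []
    n_dropped = 0
    for variant in VCF(str(path)):
        ref = variant.REF.upper()
        for alt in variant.ALT:
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                n_dropped += 1
                continue
            muts.append(Mutation(sample_id, variant.CHROM, variant.POS, ref, alt))
    if n_dropped:
        logger.warning("%s: dropped %d non-SNV allele(s)", path, n_dropped)
    if not muts:
        raise CatalogError(f"no SNV records in {path}")
    return muts


def write_context_matrix(cm: ContextMatrix, path: str | Path) -> None:
    cm.df.rename_axis("sample").to_csv(path, sep="\t")


def read_context_matrix(path: str | Path, mode: Mode) -> ContextMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ContextMatrix(df, mode=mode)


def load_tri_counts(path: str | Path) -> pd.Series:
    """Read a trinucleotide count table: TSV with columns trinucleotide, count."""
    df = pd.read_csv(path, sep="\t", dtype={"trinucleotide": str})
    if "trinucleotide" not in df.columns or "count" not in df.columns:
        raise CatalogError(f"{path}: expected columns 'trinucleotide' and 'count'")
    return validate_tri_counts(df.set_index("trinucleotide")["count"])


def bundled_tri_counts(territory: Literal["genome", "exome"]) -> pd.Series:
    """Load a bundled synthetic trinucleotide occurrence table.

    The shipped tables emulate the composition of a mammalian genome
    (AT-rich, CpG-depleted) and a protein-coding exome (more GC-rich); they
    are synthetic stand-ins generated by ``scripts/make_tri_count_tables.py``,
    not counts from any real reference build.  Supply your own table (e.g.
    from :func:`tri_counts_from_fasta` on a reference FASTA) for real
    analyses.
    """
    name = f"tri_counts_{territory}_synthetic.tsv"
    ref = resources.files("sigrefit.data").joinpath(name)
    with resources.as_file(ref) as p:
        return load_tri_counts(p)
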