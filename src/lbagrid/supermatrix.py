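"""Per-locus alignments, occupancy filtering, concatenation and rate binning.

Gene occupancy of a locus is the fraction of the full taxon set
represented by at least one unambiguous residue; all-gap or all-X rows
do not count, so padding can never inflate occupancy.  Occupancy
filtering happens once, before any taxon pruning, and is not
re-applied afterwards — loci that drop below four taxa are flagged as
untreeable but retained, mirroring the construction order of
occupancy-thresholded supermatrix families that are each pruned into a
taxon-subset series.

Evolutionary rate is proxied by mean pairwise sequence identity
(MPSI): the mean over row pairs of the fraction of identical mutually
unambiguous columns.  High identity means slow evolution, so the
tertile binning sorts by MPSI descending and splits into
slow/intermediate/fast bins whose sizes differ by at most one
(remainder assigned slow-first; ties broken by locus id).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phylo_core.models import AMBIGUOUS, AMINO_ACIDS

_VALID = set(AMINO_ACIDS) | AMBIGUOUS


@dataclass
class LocusAlignment:
    """One aligned locus: a map of terminal name to aligned row."""

    id: str
    rows: dict[str, str]

    def __post_init__(self):
        if not self.rows:
            raise ValueError(f"locus {self.id!r} has no rows")
        self.rows = {name: seq.upper() for name, seq in self.rows.items()}
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            detail = {n: len(s) for n, s in self.rows.items()}
            raise ValueError(f"locus {self.id!r} rows have unequal lengths: {detail}")
        bad = {
            name: sorted(set(seq) - _VALID)
            for name, seq in self.rows.items()
            if set(seq) - _VALID
        }
        if bad:
            raise ValueError(f"locus {self.id!r} has invalid characters: {bad}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def present_taxa(self) -> set[str]:
        """Taxa with at least one unambiguous residue."""
        return {
            name
            for name, seq in self.rows.items()
            if any(ch in AMINO_ACIDS for ch in seq)
        }


@dataclass
class SupermatrixBundle:
    alignment: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (locus id, start, end), 1-based inclusive
    taxon_order: list[str]

    @property
    def length(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0


@dataclass
class OccupancyProfile:
    threshold: float
    locus_occupancy: pd.Series
    taxon_coverage: pd.Series


@dataclass
class RateBin:
    mpsi: pd.Series  # percent, indexed by locus id
    tertile: pd.Series  # slow/intermediate/fast, same index


# ---- I/O ------------------------------------------------------------

def read_loci(directory: str | Path) -> list[LocusAlignment]:
    """Read one FASTA per locus, sorted by filename; sequences upper-cased."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in {".fa", ".fasta", ".faa"}
    )
    if not paths:
        warnings.warn(f"no FASTA files found in {directory}", RuntimeWarning, stacklevel=2)
        return []
    loci = []
    for path in paths:
        rows = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        try:
            loci.append(LocusAlignment(id=path.stem, rows=rows))
        except ValueError as err:
            raise ValueError(f"{path.name}: {err}") from err
    return loci


def write_loci(loci: list[LocusAlignment], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus in loci:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in locus.rows.items()
        ]
        SeqIO.write(records, str(directory / f"{locus.id}.fasta"), "fasta")


def write_phylip(bundle: SupermatrixBundle, path: str | Path) -> None:
    """Relaxed PHYLIP (name, two spaces, row)."""
    with open(path, "w") as fh:
        fh.write(f"{len(bundle.taxon_order)} {bundle.length}\n")
        for name in bundle.taxon_order:
            fh.write(f"{name}  {bundle.alignment[name]}\n")


def write_partitions(bundle: SupermatrixBundle, path: str | Path, model: str = "LG") -> None:
    """The common plain partition format ``MODEL, id = start-end``."""
    with open(path, "w") as fh:
        for locus_id, start, end in bundle.partitions:
            fh.write(f"{model}, {locus_id} = {start}-{end}\n")


# ---- occupancy ------------------------------------------------------

def occupancy(locus: LocusAlignment, full_taxon_set) -> float:
    """Fraction of *full_taxon_set* present in the locus with at least
    one unambiguous residue."""
    full = set(full_taxon_set)
    if not full:
        raise ValueError("full taxon set is empty")
    return len(locus.present_taxa() & full) / len(full)


def filter_by_occupancy(
    loci: list[LocusAlignment],
    threshold: float,
    full_taxon_set,
) -> tuple[list[LocusAlignment], OccupancyProfile]:
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    full = sorted(set(full_taxon_set))
    occ = pd.Series(
        {locus.id: occupancy(locus, full) for locus in loci}, dtype=float
    )
    retained = [locus for locus in loci if occ[locus.id] >= threshold]
    coverage = pd.Series(0.0, index=full)
    if retained:
        for locus in retained:
            present = locus.present_taxa()
            for t in full:
                if t in present:
                    coverage[t] += 1.0
        coverage /= len(retained)
    return retained, OccupancyProfile(
        threshold=threshold,
        locus_occupancy=occ,
        taxon_coverage=coverage,
    )


def prune_taxa(
    loci: list[LocusAlignment], keep_set
) -> tuple[list[LocusAlignment], list[str]]:
    """Restrict every locus to *keep_set*.

    The locus count is unchanged (occupancy is not re-filtered); loci
    left with fewer than 4 taxa are returned in the ``untreeable``
    list.  Loci whose rows would vanish entirely keep zero rows only
    in the flag list — they are dropped from the output.
    """
    keep = set(keep_set)
    if not keep:
        raise ValueError("keep set is empty")
    union = set().union(*(locus.rows.keys() for locus in loci)) if loci else set()
    unknown = keep - union
    if loci and unknown:
        warnings.warn(
            f"{len(unknown)} taxa in keep set absent from all loci", RuntimeWarning, stacklevel=2
        )
    out, untreeable = [], []
    for locus in loci:
        rows = {n: s for n, s in locus.rows.items() if n in keep}
        if not rows:
            untreeable.append(locus.id)
            continue
        pruned = LocusAlignment(id=locus.id, rows=rows)
        if len(rows) < 4:
            untreeable.append(locus.id)
        out.append(pruned)
    return out, untreeable


def concatenate(loci: list[LocusAlignment]) -> SupermatrixBundle:
    """Concatenate loci over the union taxon set; absent taxa are padded
    with '-' across the locus span.  Partition spans are 1-based
    inclusive and tile the total length."""
    if not loci:
        raise ValueError("nothing to concatenate")
    taxa = sorted(set().union(*(locus.rows.keys() for locus in loci)))
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for locus in loci:
        L = locus.length
        parts.append((locus.id, pos, pos + L - 1))
        pos += L
        pad = "-" * L
        for t in taxa:
            chunks[t].append(locus.rows.get(t, pad))
    alignment = {t: "".join(chunks[t]) for t in taxa}
    return SupermatrixBundle(alignment=alignment, partitions=parts, taxon_order=taxa)


# ---- rate binning ---------------------------------------------------

def mpsi(locus: LocusAlignment) -> float | None:
    """Mean percent pairwise identity over mutually unambiguous columns.

    Pairs with no comparable columns are excluded; if no pair is
    comparable the statistic is undefined and ``None`` is returned.
    """
    names = sorted(locus.rows)
    if len(names) < 2:
        raise ValueError(f"locus {locus.id!r} needs >= 2 rows for MPSI")
    arrays = {
        n: np.frombuffer(locus.rows[n].encode(), dtype="S1") for n in names
    }
    unambiguous = {
        n: np.isin(arrays[n], np.array(list(AMINO_ACIDS), dtype="S1")) for n in names
    }
    idents = []
    for a, b in itertools.combinations(names, 2):
        mask = unambiguous[a] & unambiguous[b]
        n_comp = int(mask.sum())
        if n_comp == 0:
            continue
        idents.append(float((arrays[a][mask] == arrays[b][mask]).mean()))
    if not idents:
        return None
    return 100.0 * float(np.mean(idents))


def rate_tertiles(loci: list[LocusAlignment]) -> RateBin:
    """Slow/intermediate/fast tertiles by MPSI (descending identity)."""
    values = {}
    for locus in loci:
        v = mpsi(locus)
        if v is not None:
            values[locus.id] = v
    if len(values) < 3:
        raise ValueError("need at least 3 loci with defined MPSI")
    order = sorted(values, key=lambda lid: (-values[lid], lid))
    n = len(order)
    base, extra = divmod(n, 3)
    sizes = [base + (1 if i < extra else 0) for i in range(3)]
    labels = {}
    start = 0
    for size, name in zip(sizes, ("slow", "intermediate", "fast")):
        for lid in order[start : start + size]:
            labels[lid] = name
        start += size
    idx = sorted(values)
    return RateBin(
        mpsi=pd.Series({i: values[i] for i in idx}),
        tertile=pd.Series({i: labels[i] for i in idx}),
    )
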