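"""Marker panel data structures and on-disk formats.

A *marker panel* is a set of short PCR amplicon targets over genomic loci
whose CpG sites are unmethylated in one brain cell class (neurons,
astrocytes, oligodendrocytes, or all brain cell types jointly) and
methylated in other tissues.  Counting fully unmethylated molecules at
these loci in plasma cell-free DNA measures the contribution of each
brain cell class to the circulating DNA pool.

On disk a panel is three plain-text files sharing a common stem:

``<name>.bed``
    BED-like TSV, 0-based half-open: chrom, start, end, marker_id,
    cell_type.
``<name>.fa``
    FASTA of the unconverted top-strand target sequences (one record per
    marker, record id == marker_id).
``<name>.cpgs.tsv``
    TSV with header ``marker_id\toffset``; one row per CpG cytosine,
    offsets 0-based within the target sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Recognised cell-type labels for panel amplicons.
CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte", "whole_brain", "other")

#: The three distinct brain cell classes summed into the combined brain score.
#: Whole-brain markers are reported separately (they overlap the cell-type
#: signals by construction and would double-count brain DNA if summed).
BRAIN_CELL_TYPES = ("neuron", "astrocyte", "oligodendrocyte")


@dataclasses.dataclass(frozen=True)
class AmpliconTemplate:
    """One amplicon target: unconverted top-strand sequence plus CpG map.

    Parameters
    ----------
    marker_id
        Unique marker name within the panel.
    cell_type
        One of :data:`CELL_TYPES`; the cell class in which the locus is
        specifically unmethylated.
    genomic_ref_seq
        Unconverted top-strand reference sequence (A/C/G/T only).
    cpg_offsets
        Strictly increasing 0-based positions of CpG cytosines within
        ``genomic_ref_seq``; every offset ``o`` must satisfy
        ``genomic_ref_seq[o:o+2] == "CG"``.
    chrom, start
        Optional genomic placement (synthetic panels use a dummy contig).
    """

    marker_id: str
    cell_type: str
    genomic_ref_seq: str
    cpg_offsets: tuple[int, ...]
    chrom: str = "chrSim"
    start: int = 0

    def __post_init__(self) -> None:
        seq = self.genomic_ref_seq.upper()
        object.__setattr__(self, "genomic_ref_seq", seq)
        object.__setattr__(self, "cpg_offsets", tuple(int(o) for o in self.cpg_offsets))
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell type {self.cell_type!r}")
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.marker_id}: sequence contains non-ACGT characters")
        if not self.cpg_offsets:
            raise ValueError(f"{self.marker_id}: amplicon must contain at least one CpG")
        if list(self.cpg_offsets) != sorted(set(self.cpg_offsets)):
            raise ValueError(f"{self.marker_id}: CpG offsets must be strictly increasing")
        for o in self.cpg_offsets:
            if o < 0 or o + 2 > len(seq) or seq[o : o + 2] != "CG":
                raise ValueError(f"{self.marker_id}: offset {o} is not a CG dinucleotide")

    @property
    def amplicon_length(self) -> int:
        return len(self.genomic_ref_seq)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def end(self) -> int:
        return self.start + self.amplicon_length

    def converted_target(self) -> str:
        """Fully bisulfite-converted target with CpG cytosines as ``Y``.

        Non-CpG cytosines become ``T`` (complete conversion of unmethylated
        cytosine); CpG cytosines become the IUPAC ambiguity code ``Y``
        (pyrimidine, C or T), so that reads from methylated and
        unmethylated molecules score identical similarity against the
        target during amplicon assignment.
        """
        cpg = set(self.cpg_offsets)
        return "".join(
            "Y" if i in cpg else ("T" if b == "C" else b)
            for i, b in enumerate(self.genomic_ref_seq)
        )


@dataclasses.dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of :class:`AmpliconTemplate` with unique ids."""

    amplicons: tuple[AmpliconTemplate, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        ids = [a.marker_id for a in self.amplicons]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker ids in panel")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[AmpliconTemplate]:
        return iter(self.amplicons)

    def __getitem__(self, marker_id: str) -> AmpliconTemplate:
        for a in self.amplicons:
            if a.marker_id == marker_id:
                return a
        raise KeyError(marker_id)

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(a.marker_id for a in self.amplicons)

    def markers_of(self, cell_type: str) -> tuple[AmpliconTemplate, ...]:
        return tuple(a for a in self.amplicons if a.cell_type == cell_type)

    def cell_type_of(self, marker_id: str) -> str:
        return self[marker_id].cell_type

    # ------------------------------------------------------------------ I/O

    def write(self, directory: str | Path, name: str = "panel") -> dict[str, Path]:
        """Write the BED/FASTA/CpG-offset triplet; return the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        bed = directory / f"{name}.bed"
        fasta = directory / f"{name}.fa"
        cpgs = directory / f"{name}.cpgs.tsv"

        with bed.open("w") as fh:
            for a in self.amplicons:
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.marker_id}\t{a.cell_type}\n")
        records = [
            SeqRecord(Seq(a.genomic_ref_seq), id=a.marker_id, description="")
            for a in self.amplicons
        ]
        SeqIO.write(records, str(fasta), "fasta")
        with cpgs.open("w") as fh:
            fh.write("marker_id\toffset\n")
            for a in self.amplicons:
                for o in a.cpg_offsets:
                    fh.write(f"{a.marker_id}\t{o}\n")
        return {"bed": bed, "fasta": fasta, "cpgs": cpgs}

    @classmethod
    def read(cls, directory: str | Path, name: str = "panel") -> "MarkerPanel":
        """Read a panel written by :meth:`write`."""
        directory = Path(directory)
        bed = directory / f"{name}.bed"
        fasta = directory / f"{name}.fa"
        cpgs = directory / f"{name}.cpgs.tsv"
        for p in (bed, fasta, cpgs):
            if not p.exists():
                raise FileNotFoundError(f"panel file missing: {p}")

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        offsets: dict[str, list[int]] = {}
        with cpgs.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["marker_id", "offset"]:
                raise ValueError(f"unexpected header in {cpgs}: {header}")
            for line in fh:
                mid, off = line.rstrip("\n").split("\t")[:2]
                offsets.setdefault(mid, []).append(int(off))

        amplicons = []
        with bed.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end, marker_id, cell_type = line.rstrip("\n").split("\t")[:5]
                if marker_id not in seqs:
                    raise ValueError(f"{marker_id} present in BED but absent from FASTA")
                amplicons.append(
                    AmpliconTemplate(
                        marker_id=marker_id,
                        cell_type=cell_type,
                        genomic_ref_seq=seqs[marker_id],
                        cpg_offsets=tuple(offsets.get(marker_id, ())),
                        chrom=chrom,
                        start=int(start),
                    )
                )
        return cls(tuple(amplicons))
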