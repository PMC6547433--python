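"""Gene annotations: strand-aware single-exon CDS intervals plus gene-set labels.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based inclusive)
only at the I/O boundary. Gene-set membership (ribi, dubious, paralog,
gcn4_like, luti_like, ...) travels with the annotation as a ``gene_sets``
attribute so downstream enrichment and blacklist steps need no side tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Gene", "Annotation"]


@dataclass(frozen=True)
class Gene:
    """A single-exon protein-coding gene.

    ``start``/``end`` delimit the CDS (0-based half-open, stop codon included).
    ``sets`` holds gene-set labels; ``uorf`` optionally gives the interval of a
    uORF in a 5'-extended (LUTI-like) isoform, outside the CDS.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sets: frozenset = field(default_factory=frozenset)
    uorf: tuple | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: empty CDS interval")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.end - self.start} is not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return self.end - self.start


class Annotation:
    """An ordered collection of :class:`Gene` with fast interval lookups."""

    def __init__(self, genes, chrom_sizes: dict | None = None):
        self.genes = list(genes)
        if not self.genes:
            raise ValueError("annotation must contain at least one gene")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in annotation")
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        if self.chrom_sizes is not None:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is None or g.end > size or g.start < 0:
                    raise ValueError(f"{g.gene_id}: CDS outside chromosome bounds")
        self._by_id = {g.gene_id: g for g in self.genes}
        self._check_disjoint()

    def _check_disjoint(self):
        # counting maps a position to at most one gene per (chrom, strand)
        for (_, _), sub in self._frame().groupby(["chrom", "strand"]):
            s = sub.sort_values("start")
            if (s["start"].values[1:] < s["end"].values[:-1]).any():
                raise ValueError("overlapping CDS intervals on the same strand")

    def _frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list:
        return [g.gene_id for g in self.genes]

    def in_set(self, label: str) -> list:
        """Gene ids carrying a gene-set label."""
        return [g.gene_id for g in self.genes if label in g.sets]

    def to_frame(self) -> pd.DataFrame:
        df = self._frame()
        df["cds_length"] = df["end"] - df["start"]
        df["sets"] = [",".join(sorted(g.sets)) for g in self.genes]
        return df

    # ------------------------------------------------------------------ GFF3
    def write_gff3(self, path):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            if self.chrom_sizes:
                for chrom, size in self.chrom_sizes.items():
                    fh.write(f"##sequence-region {chrom} 1 {size}\n")
            for g in self.genes:
                attrs = [f"ID={g.gene_id}"]
                if g.sets:
                    attrs.append("gene_sets=" + ",".join(sorted(g.sets)))
                if g.uorf is not None:
                    attrs.append(f"uorf_start={g.uorf[0]};uorf_end={g.uorf[1]}")
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "ribote",
                            "CDS",
                            str(g.start + 1),
                            str(g.end),
                            ".",
                            g.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )

    @classmethod
    def read_gff3(cls, path) -> "Annotation":
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        sizes = _read_sequence_regions(path)
        genes = []
        for feat in db.features_of_type("CDS", order_by="start"):
            sets = frozenset(
                s for s in feat.attributes.get("gene_sets", [""])[0].split(",") if s
            )
            uorf = None
            if "uorf_start" in feat.attributes:
                uorf = (
                    int(feat.attributes["uorf_start"][0]),
                    int(feat.attributes["uorf_end"][0]),
                )
            genes.append(
                Gene(
                    gene_id=feat.attributes["ID"][0],
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand,
                    sets=sets,
                    uorf=uorf,
                )
            )
        return cls(genes, chrom_sizes=sizes or None)


def _read_sequence_regions(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()
                sizes[chrom] = int(end)
            elif not line.startswith("#"):
                break
    return sizes
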