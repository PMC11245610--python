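"""Mutation-table ingestion and the read-support / functional-gene filters.

Mutations with fewer than 7 reads supporting the variant allele are
removed, and the remainder restricted to a functional gene list (e.g.
liver and liver-cancer specific genes). A gene qualifies as
tissue-specific when its expression in the designated tissue is at least
10-fold the median of the other tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MutationCall, TumorSample

log = logging.getLogger(__name__)

MAF_COLUMNS = ("sample_id", "gene", "chrom", "pos", "alt_reads", "total_reads")


@dataclass(frozen=True)
class GeneList:
    genes: frozenset[str]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be non-empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def read_gene_list(path: str | Path, source_tag: str = "") -> GeneList:
    """One gene symbol per line; whitespace stripped, duplicates collapsed."""
    symbols = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return GeneList(frozenset(symbols), source_tag or str(path))


class MAFFormatError(ValueError):
    pass


def read_maf_like(path: str | Path) -> list[TumorSample]:
    """Read a MAF-like TSV into one TumorSample per distinct sample id.

    Requires sample_id, gene, chrom, pos plus alt_reads and either
    total_reads or ref_reads (total = ref + alt). Positions stay 1-based.
    Malformed or invariant-breaking rows raise with the 1-based data row
    number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = set(df.columns)
    needed = {"sample_id", "gene", "chrom", "pos", "alt_reads"}
    missing = sorted(needed - cols)
    if missing:
        raise MAFFormatError(f"missing required column(s): {', '.join(missing)}")
    if "total_reads" not in cols and "ref_reads" not in cols:
        raise MAFFormatError("missing required column(s): total_reads (or ref_reads)")

    samples: dict[str, TumorSample] = {}
    for row_no, rec in enumerate(df.to_dict("records"), start=1):
        try:
            alt = int(rec["alt_reads"])
            total = int(rec["total_reads"]) if "total_reads" in cols \
                else alt + int(rec["ref_reads"])
            call = MutationCall(
                sample_id=str(rec["sample_id"]),
                gene=str(rec["gene"]).strip(),
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                alt_reads=alt,
                total_reads=total,
                major_cn=int(rec.get("major_cn", 1)),
                minor_cn=int(rec.get("minor_cn", 1)),
            )
        except (ValueError, TypeError) as exc:
            raise MAFFormatError(f"row {row_no}: {exc}") from exc
        samples.setdefault(call.sample_id, TumorSample(call.sample_id)).calls.append(call)
    return list(samples.values())


def write_maf_like(samples: list[TumorSample], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id, "gene": c.gene, "chrom": c.chrom, "pos": c.pos,
            "alt_reads": c.alt_reads, "total_reads": c.total_reads,
            "major_cn": c.major_cn, "minor_cn": c.minor_cn,
            "clone_index": "" if c.clone_index is None else c.clone_index,
        }
        for s in samples
        for c in s.calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_read_support(
    calls: list[MutationCall], min_alt: int = 7
) -> list[MutationCall]:
    """Keep mutations with at least ``min_alt`` variant-supporting reads."""
    if min_alt < 0:
        raise ValueError("min_alt must be >= 0")
    kept = [c for c in calls if c.alt_reads >= min_alt]
    if calls and not kept:
        log.warning("read-support filter removed every call")
    return kept


def filter_functional(
    calls: list[MutationCall], gene_list: GeneList
) -> list[MutationCall]:
    """Keep mutations on genes in the functional list (exact symbol match
    after whitespace stripping)."""
    return [c for c in calls if c.gene.strip() in gene_list]


def liver_specific_genes(
    expr: pd.DataFrame, liver_row: str = "Liver", fold: float = 10.0
) -> GeneList:
    """Genes expressed at least ``fold`` times the median of the non-liver
    tissues (rows = tissues, columns = genes).

    A zero non-liver median counts as specific whenever the liver value is
    positive (the ratio is treated as infinite).
    """
    if liver_row not in expr.index:
        raise ValueError(f"expression matrix has no row {liver_row!r}")
    others = expr.drop(index=liver_row)
    if len(others) < 1:
        raise ValueError("need at least one non-liver tissue")
    med = others.median(axis=0)
    liver = expr.loc[liver_row]
    keep = np.where(med > 0, liver >= fold * med, liver > 0)
    genes = frozenset(expr.columns[keep])
    return GeneList(genes, source_tag=f"{liver_row}>= {fold}x median")
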