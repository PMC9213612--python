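"""Gene-set overrepresentation testing with fold enrichment and FDR.

Given a target gene list (e.g. differentially expressed or differently
spliced genes), a reference list (all genes expressed in the tissue),
and a term → gene-set annotation, each term is scored by

    observed = |target ∩ term|
    expected = |term ∩ reference| · |target| / |reference|
    fold enrichment = observed / expected

with a two-sided Fisher exact p-value on the 2×2 table and
Benjamini–Hochberg FDR across tested terms. Fold enrichment below 1
indicates underrepresentation; both directions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentTerm",
    "fold_enrichment",
    "overrepresentation_test",
    "bh_fdr",
    "load_annotation",
    "write_enrichment_table",
]


@dataclass
class EnrichmentTerm:
    term_id: str
    term_name: str
    n_reference: int  # reference genes annotated to the term
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    fdr: float = float("nan")


def fold_enrichment(observed: float, expected: float) -> float:
    """observed / expected; the enrichment statistic of an annotation term."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return observed / expected


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = list(p_values)
    if not p:
        return []
    if any(not 0 <= x <= 1 for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def overrepresentation_test(
    target: Iterable[str],
    reference: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str] | None = None,
    min_term_size: int = 2,
) -> list[EnrichmentTerm]:
    """Fisher-exact overrepresentation test of every annotation term.

    ``target`` must be a subset of ``reference``; annotation gene sets
    are intersected with the reference before testing, and terms with
    fewer than ``min_term_size`` reference genes are skipped. Results
    are sorted by p-value.
    """
    target = set(target)
    reference = set(reference)
    stray = sorted(target - reference)
    if stray:
        shown = ", ".join(stray[:10]) + ("..." if len(stray) > 10 else "")
        raise ValueError(f"target genes missing from reference: {shown}")
    n_target = len(target)
    n_reference = len(reference)
    results: list[EnrichmentTerm] = []
    for term_id in sorted(annotation):
        term_genes = set(annotation[term_id]) & reference
        if len(term_genes) < min_term_size:
            continue
        observed = len(target & term_genes)
        expected = len(term_genes) * n_target / n_reference
        table = [
            [observed, n_target - observed],
            [len(term_genes) - observed, n_reference - n_target - len(term_genes) + observed],
        ]
        _odds, p = stats.fisher_exact(table, alternative="two-sided")
        results.append(
            EnrichmentTerm(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                n_reference=len(term_genes),
                observed=observed,
                expected=expected,
                fold_enrichment=fold_enrichment(observed, expected) if expected else float("nan"),
                p_value=float(p),
            )
        )
    adjusted = bh_fdr([t.p_value for t in results])
    for term, fdr in zip(results, adjusted):
        term.fdr = float(fdr)
    results.sort(key=lambda t: (t.p_value, t.term_id))
    return results


def load_annotation(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a term-annotation TSV (term_id, term_name, gene_id per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(required)}")
    annotation: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        annotation.setdefault(row.term_id, set()).add(row.gene_id)
        names[row.term_id] = row.term_name
    return annotation, names


def write_enrichment_table(terms: Sequence[EnrichmentTerm], path: str | Path) -> None:
    """Results TSV with observed, expected, fold enrichment, p, FDR."""
    pd.DataFrame(
        [
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "n_reference": t.n_reference,
                "observed": t.observed,
                "expected": round(t.expected, 2),
                "fold_enrichment": round(t.fold_enrichment, 2),
                "p_value": t.p_value,
                "fdr": t.fdr,
            }
            for t in terms
        ]
    ).to_csv(path, sep="\t", index=False)
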