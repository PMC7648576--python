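"""Screen-level bookkeeping: scorer reconciliation, hit-table tabulation,
functional enrichment, and coverage arithmetic.

A genetic screen of temperature-sensitive mutants is scored by two
independent investigators; a third resolves disagreements.  Hits are
collected in a gene table assigning each gene a phenotype class (I: partial
loss of reporter asymmetry; II: reporter present in all nuclei at every cell
cycle stage; III: symmetric reporter restricted to late mitosis) and a
functional category.  Enrichment of hit genes in a functional category is a
one-sided Fisher's exact test against a user-supplied background annotation;
no ontology traversal or live database access is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

CLASSES = ("I", "II", "III")
CALLS = ("asymmetric", "symmetric", "unscorable")


@dataclass(frozen=True)
class GeneRecord:
    gene: str
    alleles: tuple[str, ...]
    phenotype_class: str
    function_category: str
    mitotic_flag: bool = False

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"gene {self.gene}: at least one allele required")
        if self.phenotype_class not in CLASSES:
            raise ValueError(f"gene {self.gene}: unknown class {self.phenotype_class!r}")


@dataclass(frozen=True)
class ScoreRecord:
    strain_id: str
    scorer_a: str
    scorer_b: str
    scorer_c: str | None
    consensus: str | None  # None = unresolved


@dataclass(frozen=True)
class ClassSummary:
    n_genes: int
    n_alleles: int
    class_counts: dict[str, int]
    class_percent: dict[str, int]
    function_counts: dict[str, int]
    function_percent: dict[str, int]


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # hits in category
    n: int  # total hits
    K: int  # background genes in category
    N: int  # background total
    fold_enrichment: float
    p_value: float


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves away from zero (reporting style)."""
    import math
    return int(math.floor(x + 0.5))


def reconcile_scores(calls_a: Mapping[str, str], calls_b: Mapping[str, str],
                     calls_c: Mapping[str, str] | None = None) -> list[ScoreRecord]:
    """Reconcile two independent scorers, with a third resolving discrepancies.

    Agreement between A and B is the consensus; on disagreement the third
    scorer's call decides, or the strain is left unresolved if absent.  Inputs
    are mappings strain_id -> call; pandas Series (which surface duplicate
    strain ids) are accepted and checked.
    """
    calls_c = calls_c or {}
    a, b, c = (_as_call_dict(m, name) for m, name in
               ((calls_a, "scorer_a"), (calls_b, "scorer_b"), (calls_c, "scorer_c")))
    records = []
    for strain in sorted(set(a) | set(b)):
        ca, cb = a.get(strain, "unscorable"), b.get(strain, "unscorable")
        cc = c.get(strain)
        if ca == cb:
            consensus = ca
        elif cc is not None:
            consensus = cc
        else:
            consensus = None
        records.append(ScoreRecord(strain, ca, cb, cc, consensus))
    return records


def _as_call_dict(calls: Mapping[str, str], name: str) -> dict[str, str]:
    if isinstance(calls, pd.Series):
        if calls.index.has_duplicates:
            dupes = sorted(calls.index[calls.index.duplicated()].unique())
            raise ValueError(f"{name}: duplicate strain ids {dupes}")
        calls = calls.to_dict()
    out = dict(calls)
    bad = {v for v in out.values() if v not in CALLS}
    if bad:
        raise ValueError(f"{name}: unknown calls {sorted(bad)}")
    return out


def packaged_gene_table() -> Path:
    """Path to the screen hit-gene table shipped with the package."""
    return Path(str(resources.files("asympart").joinpath("data/table1_genes.tsv")))


def load_gene_table(path: str | Path | None = None) -> list[GeneRecord]:
    """Load a TSV hit-gene table (columns: gene, alleles, class, function,
    mitotic_flag); defaults to the packaged screen table.

    Alleles are comma-separated.  Duplicate gene symbols and unknown class
    tokens are rejected with the offending line number.
    """
    path = Path(path) if path is not None else packaged_gene_table()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "alleles", "class", "function", "mitotic_flag"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    df = df.rename(columns={"class": "phenotype_class"})
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        if row.gene in seen:
            raise ValueError(f"{path}:{i}: duplicate gene {row.gene!r}")
        if row.phenotype_class not in CLASSES:
            raise ValueError(f"{path}:{i}: unknown class token {row.phenotype_class!r}")
        seen.add(row.gene)
        records.append(GeneRecord(
            gene=row.gene,
            alleles=tuple(a.strip() for a in row.alleles.split(",") if a.strip()),
            phenotype_class=row.phenotype_class,
            function_category=row.function,
            mitotic_flag=str(row.mitotic_flag).strip().lower() in ("true", "1", "yes")))
    return records


def tabulate_classes(records: Sequence[GeneRecord]) -> ClassSummary:
    """Per-class and per-function gene counts with half-up integer percentages."""
    if not records:
        raise ValueError("need at least one gene record")
    n = len(records)
    class_counts = {c: sum(r.phenotype_class == c for r in records) for c in CLASSES}
    func_counts: dict[str, int] = {}
    for r in records:
        func_counts[r.function_category] = func_counts.get(r.function_category, 0) + 1
    return ClassSummary(
        n_genes=n,
        n_alleles=sum(len(r.alleles) for r in records),
        class_counts=class_counts,
        class_percent={c: round_half_up(100 * k / n) for c, k in class_counts.items()},
        function_counts=dict(sorted(func_counts.items())),
        function_percent={f: round_half_up(100 * k / n)
                          for f, k in sorted(func_counts.items())})


def functional_enrichment(hit_genes: Iterable[str],
                          background_annotation: Mapping[str, str | Iterable[str]],
                          ) -> tuple[list[EnrichmentResult], list[str]]:
    """Per-category enrichment of hit genes against a background annotation.

    ``background_annotation`` maps every background gene to one category (or
    an iterable of categories).  Hits not present in the background are
    dropped and returned separately.  For each category with k of n hits and
    K of N background genes: fold = (k/n)/(K/N) and a one-sided (greater)
    Fisher's exact p-value on [[k, n-k], [K-k, N-n-(K-k)]].  Results are
    sorted by p-value.
    """
    if not background_annotation:
        raise ValueError("background annotation is empty")
    bg_cats: dict[str, set[str]] = {}
    for gene, cats in background_annotation.items():
        bg_cats[gene] = {cats} if isinstance(cats, str) else set(cats)

    hits = list(dict.fromkeys(hit_genes))
    dropped = [g for g in hits if g not in bg_cats]
    hits = [g for g in hits if g in bg_cats]
    n, N = len(hits), len(bg_cats)

    categories = sorted({c for cats in bg_cats.values() for c in cats})
    results = []
    for cat in categories:
        K = sum(cat in cats for cats in bg_cats.values())
        k = sum(cat in bg_cats[g] for g in hits)
        fold = (k / n) / (K / N) if n and K else float("nan")
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        _, p = sps.fisher_exact(table, alternative="greater")
        results.append(EnrichmentResult(cat, k, n, K, N, fold, float(p)))
    results.sort(key=lambda r: (r.p_value, r.category))
    return results, dropped


def screen_coverage(scored: int, total: int) -> int:
    """Percentage of strains scored, rounded half-up to an integer."""
    if not (0 <= scored <= total) or total < 1:
        raise ValueError("require 0 <= scored <= total and total >= 1")
    return round_half_up(100 * scored / total)
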