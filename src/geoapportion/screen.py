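"""Taxonomic screen for putative geosmin-producer clades.

Operates on an OTU count table (rows = OTUs, columns = samples) plus a
ranked lineage per OTU. Producer clades are matched by an ordered rule
list, most specific rank first, so a genus-level carve-out (e.g.
Streptomyces) wins over its parent order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Ranked lineage for one OTU.

    Ranks may be empty from any point downward but a filled rank must not
    sit below a gap (no "holes" in the lineage).
    """

    otu_id: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.lineage)}")
        seen_empty = False
        for name in self.lineage:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"malformed lineage for {self.otu_id}: filled rank below an empty one"
                )

    def at(self, rank: str) -> str:
        return self.lineage[_RANK_INDEX[rank]]


@dataclass(frozen=True)
class ProducerRule:
    """Match a lineage name at one rank to a producer group label."""

    rank: str
    name: str
    group_label: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")


#: Screening rules in precedence order: genus carve-outs first, then
#: order-level clades, then the phylum-level cyanobacterial catch-all.
DEFAULT_PRODUCER_RULES = (
    ProducerRule("genus", "Streptomyces", "Streptomyces"),
    ProducerRule("genus", "Sorangium", "Sorangium"),
    ProducerRule("order", "Myxococcales", "Myxococcales"),
    ProducerRule("order", "Actinomycetales", "Actinomycetales"),
    ProducerRule("phylum", "Cyanobacteria", "Cyanobacteria"),
)


def flag_putative_producer(
    assignment: TaxonomyAssignment,
    rules: Sequence[ProducerRule] = DEFAULT_PRODUCER_RULES,
) -> str | None:
    """Return the producer group of the first matching rule, or None.

    Matching is case-insensitive exact comparison of the rank name.
    """
    if not rules:
        raise ValueError("rule list must be non-empty")
    for rule in rules:
        if assignment.at(rule.rank).lower() == rule.name.lower():
            return rule.group_label
    return None


def _relative_abundance(otu_table: pd.DataFrame) -> pd.DataFrame:
    totals = otu_table.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        warnings.warn(f"excluding zero-read samples: {zero}", stacklevel=3)
        otu_table = otu_table.drop(columns=zero)
        totals = totals.drop(index=zero)
    return otu_table / totals


def producer_abundance_table(
    otu_table: pd.DataFrame,
    taxonomy: Mapping[str, TaxonomyAssignment],
    sample_groups: Mapping[str, str],
    rules: Sequence[ProducerRule] = DEFAULT_PRODUCER_RULES,
) -> pd.DataFrame:
    """Min-max relative abundance (%) of each producer group per sample type.

    Per sample, a group's relative abundance is the read-count sum over
    its OTUs divided by the sample total. Groups absent everywhere report
    0.0% for both bounds. Samples with zero total reads are excluded with
    a warning.
    """
    if (otu_table.values < 0).any():
        raise ValueError("counts must be non-negative")
    missing = set(otu_table.columns) - set(sample_groups)
    if missing:
        raise ValueError(f"samples without a sample type: {sorted(missing)}")
    rel = _relative_abundance(otu_table.astype(float))

    group_labels = list(dict.fromkeys(r.group_label for r in rules))
    otu_group = {
        otu: flag_putative_producer(taxonomy[otu], rules) if otu in taxonomy else None
        for otu in rel.index
    }

    records = []
    sample_types = sorted(set(sample_groups[s] for s in rel.columns))
    for label in group_labels:
        otus = [o for o, g in otu_group.items() if g == label]
        per_sample = rel.loc[otus].sum(axis=0) if otus else pd.Series(0.0, index=rel.columns)
        for stype in sample_types:
            cols = [s for s in rel.columns if sample_groups[s] == stype]
            vals = 100.0 * per_sample[cols]
            records.append(
                {
                    "group": label,
                    "sample_type": stype,
                    "min_pct": float(vals.min()) if cols else 0.0,
                    "max_pct": float(vals.max()) if cols else 0.0,
                }
            )
    return pd.DataFrame.from_records(records)


def top_taxa(
    otu_table: pd.DataFrame,
    n: int = 15,
    sample_groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """The ``n`` most abundant OTUs by mean relative abundance.

    Ties break by total reads, then by OTU id. When ``sample_groups`` is
    given, the returned matrix holds mean proportions per sample type;
    otherwise per-sample proportions. Requesting more OTUs than exist
    returns them all (flagged via ``attrs["truncated"]``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = _relative_abundance(otu_table.astype(float))
    mean_rel = rel.mean(axis=1)
    totals = otu_table.sum(axis=1)
    order = sorted(
        rel.index,
        key=lambda o: (-mean_rel[o], -totals[o], str(o)),
    )
    truncated = n > len(order)
    top = order[: min(n, len(order))]
    sub = rel.loc[top]
    if sample_groups is not None:
        cols = {}
        for stype in sorted(set(sample_groups[s] for s in sub.columns)):
            members = [s for s in sub.columns if sample_groups[s] == stype]
            cols[stype] = sub[members].mean(axis=1)
        sub = pd.DataFrame(cols)
    sub.attrs["truncated"] = truncated
    return sub


def richness(counts: Sequence[float]) -> tuple[int, float]:
    """Observed OTU count and the bias-corrected Chao1 estimate.

    chao1 = S_obs + F1*(F1 - 1) / (2*(F2 + 1)) with F1 singletons and F2
    doubletons; reduces to S_obs when no singletons exist.
    """
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        as_float = arr.astype(float)
        if not np.allclose(as_float, np.round(as_float)):
            raise ValueError("counts must be integers")
        arr = np.round(as_float).astype(int)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs, chao1


def parse_lineage(text: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage, stripping rank prefixes.

    Accepts ``k__Bacteria;p__Cyanobacteria;...`` or bare names; shorter
    lineages are padded with empty ranks.
    """
    parts = [p.strip() for p in text.split(";")]
    cleaned = []
    for p in parts:
        if len(p) >= 3 and p[1:3] == "__":
            p = p[3:]
        cleaned.append(p)
    cleaned = cleaned[: len(RANKS)]
    cleaned += [""] * (len(RANKS) - len(cleaned))
    return tuple(cleaned)
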