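"""Benchmark summaries over an externally supplied clone panel.

The published supplementary tables of a clone-resolved LTSP study are not
redistributed here; once exported to the package's flat formats (a per-clone
mutation TSV and a clone metadata TSV, see :mod:`ltspop.catalog`), this
module recomputes the headline counts — unique mutations, category
breakdown, unique genotypes, per-lineage clone shares, mean mutation burden
on the final day, and Ka/Ks when codon pairs are available.
"""
from __future__ import annotations

from typing import Optional

import numpy as np

from .catalog import (CloneRecord, apply_qc_filters, build_catalog,
                      read_clone_table, read_mutation_table, QCConfig)
from .lineage import assign_lineages, build_mst, collapse_genotypes
from .selection import kaks_estimate
from .trajectories import clone_lineage_labels


def benchmark_counts(mutation_tsv, clone_tsv,
                     qc: Optional[QCConfig] = None,
                     codon_pairs=None) -> dict:
    """Recompute headline panel summaries from flat input tables."""
    calls = read_mutation_table(mutation_tsv)
    clones = read_clone_table(clone_tsv)
    clones = [CloneRecord(c.clone_id, c.culture, c.day, c.mean_depth,
                          calls.get(c.clone_id, []))
              for c in clones]
    clones, report = apply_qc_filters(clones, qc or QCConfig())
    catalog = build_catalog(clones)
    genotypes = collapse_genotypes(catalog.matrix, clones)
    mst = build_mst(genotypes)
    assignment = assign_lineages(mst)
    labels = clone_lineage_labels(catalog.matrix, genotypes, assignment)
    n_clones = len(clones)
    shares = {}
    for lab in sorted(set(labels.values())):
        shares[lab] = sum(1 for v in labels.values() if v == lab) / n_clones
    final_day = max(c.day for c in clones)
    burden = [len(c.mutations) for c in clones if c.day == final_day]
    out = {
        "n_clones": n_clones,
        "n_unique_mutations": len(catalog.records),
        "category_counts": catalog.category_counts,
        "n_genotypes": sum(1 for g in genotypes if g.clone_count > 0),
        "lineage_clone_shares": shares,
        "final_day": final_day,
        "final_day_mean_mutations": float(np.mean(burden)),
        "filter_report": report.__dict__,
    }
    if codon_pairs:
        out["kaks_li93"] = kaks_estimate(codon_pairs, method="Li93").ratio
        out["kaks_ng86"] = kaks_estimate(codon_pairs, method="NG86").ratio
    return out
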