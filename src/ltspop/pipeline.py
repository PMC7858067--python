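"""One-call analysis bundle: catalog -> genotypes -> MST -> lineages -> sweeps."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .catalog import (CloneRecord, FilterReport, MutationCatalog, QCConfig,
                      apply_qc_filters, build_catalog)
from .lineage import (GenotypeMst, GenotypeNode, LineageAssignment,
                      assign_lineages, build_mst, classify_core_collateral,
                      collapse_genotypes, detect_reversions)
from .trajectories import (FixationEvent, annotate_cofixation_groups,
                           clone_lineage_labels, fixation_events)


@dataclass
class AnalysisResult:
    clones: list[CloneRecord]
    filter_report: FilterReport
    catalog: MutationCatalog
    genotypes: list[GenotypeNode]
    mst: GenotypeMst
    assignment: LineageAssignment
    clone_labels: dict[str, str]
    fixations: list[FixationEvent]

    @property
    def matrix(self) -> pd.DataFrame:
        return self.catalog.matrix

    def core_mutations(self) -> dict[str, set[str]]:
        core: dict[str, set[str]] = {}
        for e in self.fixations:
            core.setdefault(e.lineage, set()).add(e.mutation_id)
        return core


def analyze_clones(clones: Sequence[CloneRecord],
                   qc: Optional[QCConfig] = None,
                   min_persistence_days: int = 150,
                   sublineage_min_clones: int = 10,
                   min_n: int = 5) -> AnalysisResult:
    """Run the full clone-panel analysis with default parameters."""
    filtered, report = apply_qc_filters(clones, qc or QCConfig())
    catalog = build_catalog(filtered)
    genotypes = collapse_genotypes(catalog.matrix, filtered)
    mst = build_mst(genotypes)
    assignment = assign_lineages(mst,
                                 min_persistence_days=min_persistence_days)
    labels = clone_lineage_labels(catalog.matrix, genotypes, assignment)
    events = annotate_cofixation_groups(
        fixation_events(catalog.matrix, filtered, labels, min_n=min_n,
                        mst=mst))
    result = AnalysisResult(clones=filtered, filter_report=report,
                            catalog=catalog, genotypes=genotypes, mst=mst,
                            assignment=assignment, clone_labels=labels,
                            fixations=events)
    classify_core_collateral(mst, assignment, result.core_mutations(),
                             sublineage_min_clones=sublineage_min_clones)
    detect_reversions(mst, assignment)
    return result
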