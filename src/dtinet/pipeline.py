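"""End-to-end orchestration: DWI -> tensors -> tracking -> network -> stats."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import (ConnectomeMatrix, LabelVolume, assign_endpoints,
                         build_matrix, component_size_sweep)
from .laterality import AsymmetryReport, run_asymmetry_analysis
from .metrics import NodalMetrics, compute_nodal_metrics
from .phantom import CohortSpec, GroundTruth, generate_cohort, ground_truth_of
from .tensor import DWIVolume, FAMap, compute_fa, fit_tensor
from .tracking import StreamlineSet, TrackingParams, track_fact
from .tracts import TractProtocol, TractStats, select_tract, tract_stats

__all__ = ["SubjectResult", "CohortAnalysis", "process_subject", "analyze_cohort"]


@dataclass
class SubjectResult:
    subject_id: str
    fa: FAMap
    streamlines: StreamlineSet
    connectome: ConnectomeMatrix
    metrics: NodalMetrics
    tracts: list[TractStats] = field(default_factory=list)


@dataclass
class CohortAnalysis:
    report: AsymmetryReport
    subjects: list[SubjectResult]
    ground_truth: GroundTruth
    component_sweep: dict[int, float]


def process_subject(labels: LabelVolume, dwi: DWIVolume,
                    tracking_params: TrackingParams | None = None,
                    edge_threshold: int = 3,
                    protocols: list[TractProtocol] | None = None,
                    subject_id: str = "subject") -> SubjectResult:
    """Run the single-subject chain from raw DWI to nodal metrics."""
    tensors = fit_tensor(dwi)
    fa = compute_fa(tensors)
    streamlines = track_fact(tensors, fa, tracking_params)
    assignments = assign_endpoints(streamlines, labels)
    conn = build_matrix(assignments, labels.n_regions, edge_threshold)
    metrics = compute_nodal_metrics(conn.adjacency)
    tract_list: list[TractStats] = []
    for protocol in protocols or []:
        subset = select_tract(streamlines, protocol)
        tract_list.append(
            tract_stats(subset, fa, name=protocol.name, hemisphere=protocol.hemisphere)
        )
    return SubjectResult(
        subject_id=subject_id, fa=fa, streamlines=streamlines,
        connectome=conn, metrics=metrics, tracts=tract_list,
    )


def analyze_cohort(spec: CohortSpec,
                   tracking_params: TrackingParams | None = None,
                   edge_threshold: int = 3,
                   protocols: list[TractProtocol] | None = None,
                   alpha: float = 0.05,
                   keep_volumes: bool = False,
                   sweep_thresholds=range(1, 6)) -> CohortAnalysis:
    """Simulate a cohort, process every subject, and run the group analysis."""
    import warnings

    results: list[SubjectResult] = []
    for subject in generate_cohort(spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-subject trackability warnings
            res = process_subject(
                subject.labels, subject.dwi, tracking_params, edge_threshold,
                protocols, subject.subject_id,
            )
        if not keep_volumes:
            res.fa = None  # type: ignore[assignment]
            res.streamlines = None  # type: ignore[assignment]
        results.append(res)
    report = run_asymmetry_analysis(
        [r.metrics for r in results],
        [r.tracts for r in results] if protocols else None,
        alpha=alpha,
    )
    sweep = component_size_sweep(
        [r.connectome.fiber_counts for r in results], sweep_thresholds
    )
    return CohortAnalysis(
        report=report, subjects=results,
        ground_truth=ground_truth_of(spec), component_sweep=sweep,
    )
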