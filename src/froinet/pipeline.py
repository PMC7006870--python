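"""End-to-end driver: simulate/read -> activate -> networks -> group ->
k-core occupancy -> rich club, with deterministic seeding and a JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._rng import child_seed
from .activation import ActivationMap, activation_map
from .cohort import CohortSpec, SubjectData, simulate_cohort
from .design import TaskDesign, canonical_hrf, default_design, make_regressor
from .errors import PipelineStageError
from .group import build_common_network, pooled_weight_distribution, rank_froi_strength
from .io import (
    PipelineConfig,
    read_subject,
    write_common_network,
    write_froi_network,
    write_subject,
    write_voxel_network,
)
from .kcore import core_decompose, null_occupancy, occupancy_by_froi
from .networks import (
    FROINetwork,
    VoxelNetwork,
    aggregate_froi,
    correlation_matrix,
    normalize_weights,
    threshold_network,
)
from .richclub import threshold_sensitivity

logger = logging.getLogger("froinet")

__all__ = ["SubjectResult", "analyze_subject", "run_pipeline"]


@dataclass
class SubjectResult:
    """All per-subject stage outputs for one subject."""

    subject: SubjectData
    amap: ActivationMap
    vnet: VoxelNetwork | None
    fnet: FROINetwork | None


def analyze_subject(
    subject: SubjectData,
    regressor: np.ndarray,
    theta: float,
    p_thresh: float = 1e-4,
    q_thresh: float = 1e-3,
    exclude_frois: tuple[str, ...] = (),
) -> SubjectResult:
    """Activation map -> active-voxel network -> normalized fROI network.

    Subjects with fewer than 2 active voxels get ``vnet = fnet = None``.
    """
    amap = activation_map(
        subject,
        regressor,
        p_thresh=p_thresh,
        q_thresh=q_thresh,
        exclude_frois=exclude_frois,
    )
    mask = amap.active
    if mask.sum() < 2:
        return SubjectResult(subject=subject, amap=amap, vnet=None, fnet=None)
    corr = correlation_matrix(subject.bold[mask])
    vnet = threshold_network(
        corr,
        subject.labels[mask],
        theta,
        voxel_ids=np.asarray(subject.voxel_ids)[mask],
    )
    fnet = normalize_weights(aggregate_froi(vnet, subject_id=subject.subject_id))
    return SubjectResult(subject=subject, amap=amap, vnet=vnet, fnet=fnet)


def _stage(name: str, subject_id: str | None = None):
    """Decorator-free stage guard used inline via try/except below."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write TSV/JSON/GraphML outputs under ``out_dir``.

    Deterministic: identical configs produce byte-identical outputs. Returns
    the report dict (also written as ``report.json``).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = default_design()
    kernel = canonical_hrf(design.tr_seconds)
    regressor = make_regressor(design, kernel)

    # --- subjects: simulate or read ---
    if config.input_dir is None:
        try:
            spec = CohortSpec(n_subjects=config.n_subjects, seed=child_seed(config.seed, "cohort"))
            subjects = simulate_cohort(spec, design, kernel)
            for subject in subjects:
                write_subject(out_dir / "subjects", subject, design)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("simulate", None, exc) from exc
    else:
        subjects = []
        in_dir = Path(config.input_dir)
        for bold_path in sorted(in_dir.glob("*_bold.tsv")):
            sid = bold_path.name.replace("_bold.tsv", "")
            labels_path = in_dir / f"{sid}_labels.tsv"
            sidecar = in_dir / f"{sid}_sidecar.json"
            try:
                subjects.append(
                    read_subject(
                        bold_path, labels_path, sidecar if sidecar.exists() else None, subject_id=sid
                    )
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError("read", sid, exc) from exc
        if not subjects:
            raise PipelineStageError("read", None, FileNotFoundError("no *_bold.tsv in input_dir"))

    # --- per-subject stages ---
    results: list[SubjectResult] = []
    for subject in subjects:
        try:
            res = analyze_subject(
                subject,
                regressor,
                theta=config.theta,
                p_thresh=config.p_thresh,
                q_thresh=config.q_thresh,
                exclude_frois=config.exclude_frois,
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("network", subject.subject_id, exc) from exc
        results.append(res)
        net_dir = out_dir / "networks"
        act_dir = out_dir / "activation"
        act_dir.mkdir(parents=True, exist_ok=True)
        res.amap.to_frame().to_csv(
            act_dir / f"{subject.subject_id}_activation.tsv", sep="\t", index=False
        )
        if res.vnet is not None:
            write_voxel_network(net_dir, res.vnet, subject.subject_id)
        if res.fnet is not None:
            write_froi_network(net_dir, res.fnet, subject.subject_id)
        logger.info(
            "subject %s: %d active voxels, %d voxel edges",
            subject.subject_id,
            int(res.amap.active.sum()),
            res.vnet.n_edges if res.vnet else 0,
        )

    fnets = [r.fnet for r in results if r.fnet is not None]
    if len(fnets) < 2:
        raise PipelineStageError("common", None, ValueError("fewer than 2 usable subjects"))

    # --- group stage ---
    try:
        cnet = build_common_network(
            fnets, presence_fraction=config.presence_fraction, denominator=config.eq4_denominator
        )
        write_common_network(out_dir, cnet)
        rank_frames = []
        for r in results:
            if r.fnet is not None and r.fnet.n_edges > 0:
                df = rank_froi_strength(r.fnet)
                df.insert(0, "subject", r.subject.subject_id)
                rank_frames.append(df)
        if rank_frames:
            import pandas as pd

            pd.concat(rank_frames, ignore_index=True).to_csv(
                out_dir / "froi_strength_ranks.tsv", sep="\t", index=False
            )
        wdist = pooled_weight_distribution(fnets)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("common", None, exc) from exc

    # --- k-core occupancy + permutation null ---
    try:
        pairs = []
        for r in results:
            if r.vnet is None or r.vnet.n_edges == 0:
                continue
            pairs.append((core_decompose(r.vnet), r.vnet.labels()))
        occupancy_frois = (
            tuple(sorted(cnet.graph.nodes()))
            if config.occupancy_frois is None and cnet.graph.number_of_nodes() > 0
            else config.occupancy_frois
        )
        occ = occupancy_by_froi(pairs, froi_filter=occupancy_frois, n_bins=config.n_bins)
        occ.to_frame().to_csv(out_dir / "kshell_occupancy.tsv", sep="\t", index=False)
        null = null_occupancy(
            pairs,
            froi_filter=occupancy_frois,
            n_perm=config.n_perm,
            seed=child_seed(config.seed, "kcore-null"),
        )
        null.to_frame().to_csv(out_dir / "kshell_null.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("kcore", None, exc) from exc

    # --- rich club on the first usable subject (representative) ---
    sweep_summary = None
    try:
        rep = next((r for r in results if r.vnet is not None and r.vnet.n_edges >= 2), None)
        if rep is not None:
            mask = rep.amap.active
            sweep = threshold_sensitivity(
                rep.subject.bold[mask],
                rep.subject.labels[mask],
                theta0=config.theta,
                deltas=config.deltas,
                n_null=config.n_null,
                n_swaps=config.n_swaps,
                seed=child_seed(config.seed, "richclub"),
            )
            for delta, curve in sweep.curves.items():
                curve.to_frame().to_csv(
                    out_dir / f"richclub_{rep.subject.subject_id}_delta{delta:+.2f}.tsv",
                    sep="\t",
                    index=False,
                )
            sweep_summary = {
                "subject": rep.subject.subject_id,
                "slopes": {f"{d:+.2f}": s for d, s in sorted(sweep.slopes.items())},
                "qualitative_agreement": sweep.qualitative_agreement,
            }
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("richclub", rep.subject.subject_id if rep else None, exc) from exc

    report = {
        "config": config.to_dict(),
        "seeds": {
            "master": config.seed,
            "cohort": child_seed(config.seed, "cohort"),
            "kcore_null": child_seed(config.seed, "kcore-null"),
            "richclub": child_seed(config.seed, "richclub"),
        },
        "n_subjects": len(subjects),
        "n_usable_subjects": len(fnets),
        "subjects": {
            r.subject.subject_id: {
                "n_voxels": int(r.subject.n_voxels),
                "n_active": int(r.amap.active.sum()),
                "n_voxel_edges": r.vnet.n_edges if r.vnet else 0,
                "n_froi_edges": r.fnet.n_edges if r.fnet else 0,
            }
            for r in results
        },
        "common_network": {
            "frois": sorted(cnet.graph.nodes()),
            "edges": [
                {
                    "froi_i": min(u, v),
                    "froi_j": max(u, v),
                    "W_C": round(data["weight"], 6),
                    "sd": round(data["sd"], 6),
                    "n_present": data["n_present"],
                }
                for u, v, data in sorted(
                    cnet.graph.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))
                )
            ],
        },
        "weight_distribution": {
            "skewness": round(wdist.skewness, 6),
            "n_edges": wdist.n_edges,
        },
        "kshell": {
            froi: {
                "max_shell_fraction": round(occ.max_shell_fraction[froi], 6),
                "null_mean": round(null.null_mean[froi], 6),
                "null_sd": round(null.null_sd[froi], 6),
                "p": round(null.p_value[froi], 6),
            }
            for froi in sorted(occ.max_shell_fraction)
        },
        "rich_club": sweep_summary,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
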