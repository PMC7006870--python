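"""Plain-text I/O: subject TSVs, network exports, and configuration files.

All artifacts are TSV / JSON / GraphML. A subject is stored as a BOLD TSV
(rows = voxels, columns = volumes, header row of volume indices, first
column ``voxel_id``), a two-column labels TSV (``voxel_id``, ``froi_name``),
and an optional JSON sidecar holding the task design, seeds, and ground
truth. The voxel order of the labels file is authoritative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import SubjectData
from .design import TaskDesign
from .errors import SubjectIOError
from .group import CommonNetwork
from .networks import FROINetwork, VoxelNetwork

__all__ = [
    "write_subject",
    "read_subject",
    "write_voxel_network",
    "write_froi_network",
    "write_common_network",
    "PipelineConfig",
    "load_config",
]

_READ_KW = dict(sep="\t", encoding="utf-8-sig")  # tolerates BOM; CRLF handled natively


def write_subject(out_dir: str | Path, subject: SubjectData, design: TaskDesign | None = None) -> dict[str, Path]:
    """Write bold/labels TSVs plus a JSON sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    bold_path = out_dir / f"{sid}_bold.tsv"
    labels_path = out_dir / f"{sid}_labels.tsv"
    sidecar_path = out_dir / f"{sid}_sidecar.json"

    bold_df = pd.DataFrame(
        subject.bold,
        index=pd.Index(subject.voxel_ids, name="voxel_id"),
        columns=[str(i) for i in range(subject.n_volumes)],
    )
    bold_df.to_csv(bold_path, sep="\t")
    pd.DataFrame(
        {"voxel_id": subject.voxel_ids, "froi_name": subject.labels.astype(str)}
    ).to_csv(labels_path, sep="\t", index=False)

    sidecar: dict = {"subject_id": sid}
    if design is not None:
        sidecar["design"] = {
            "epochs": [list(e) for e in design.epochs],
            "tr_seconds": design.tr_seconds,
        }
    if subject.truth_active is not None:
        sidecar["truth_active"] = [bool(a) for a in subject.truth_active]
    if subject.truth_beta is not None:
        sidecar["truth_beta"] = [float(b) for b in subject.truth_beta]
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {"bold": bold_path, "labels": labels_path, "sidecar": sidecar_path}


def read_subject(
    bold_path: str | Path,
    labels_path: str | Path,
    sidecar_path: str | Path | None = None,
    subject_id: str | None = None,
) -> SubjectData:
    """Read a subject back; the labels file's voxel order is authoritative."""
    bold_df = pd.read_csv(bold_path, index_col=0, **_READ_KW)
    labels_df = pd.read_csv(labels_path, **_READ_KW)
    if list(labels_df.columns[:2]) != ["voxel_id", "froi_name"]:
        raise SubjectIOError("labels file must have columns voxel_id, froi_name")
    if labels_df["voxel_id"].duplicated().any():
        raise SubjectIOError("duplicate voxel ids in labels file")
    if bold_df.index.duplicated().any():
        raise SubjectIOError("duplicate voxel ids in bold file")
    if len(labels_df) != len(bold_df):
        raise SubjectIOError(
            f"row-count mismatch: {len(bold_df)} bold rows vs {len(labels_df)} labels"
        )
    missing = set(labels_df["voxel_id"]) - set(bold_df.index)
    if missing:
        raise SubjectIOError(f"voxels in labels but not in bold: {sorted(missing)[:5]}")
    bold = bold_df.loc[labels_df["voxel_id"]].to_numpy(dtype=float)

    truth_active = truth_beta = None
    if sidecar_path is not None:
        sidecar = json.loads(Path(sidecar_path).read_text())
        subject_id = subject_id or sidecar.get("subject_id")
        if "truth_active" in sidecar:
            truth_active = np.array(sidecar["truth_active"], dtype=bool)
        if "truth_beta" in sidecar:
            truth_beta = np.array(sidecar["truth_beta"], dtype=float)
    return SubjectData(
        subject_id=subject_id or Path(bold_path).stem.replace("_bold", ""),
        bold=bold,
        labels=labels_df["froi_name"].to_numpy(dtype=object),
        voxel_ids=labels_df["voxel_id"].to_numpy(),
        truth_active=truth_active,
        truth_beta=truth_beta,
    )


def _ordered_edge(u, v):
    return (u, v) if str(u) <= str(v) else (v, u)


def write_voxel_network(out_dir: str | Path, vnet: VoxelNetwork, stem: str) -> dict[str, Path]:
    """Edge-list + node TSVs and a GraphML export for one voxel network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [
            {"voxel_i": a, "voxel_j": b, "weight": data["weight"]}
            for u, v, data in vnet.graph.edges(data=True)
            for a, b in [_ordered_edge(u, v)]
        ],
        columns=["voxel_i", "voxel_j", "weight"],
    ).sort_values(["voxel_i", "voxel_j"], ignore_index=True)
    nodes = pd.DataFrame(
        [{"voxel_id": v, "froi": froi} for v, froi in sorted(vnet.graph.nodes(data="froi"), key=lambda t: str(t[0]))],
        columns=["voxel_id", "froi"],
    )
    edge_path = out_dir / f"{stem}_edges.tsv"
    node_path = out_dir / f"{stem}_nodes.tsv"
    gml_path = out_dir / f"{stem}.graphml"
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes.to_csv(node_path, sep="\t", index=False)
    nx.write_graphml(vnet.graph, gml_path)
    return {"edges": edge_path, "nodes": node_path, "graphml": gml_path}


def write_froi_network(out_dir: str | Path, fnet: FROINetwork, stem: str) -> dict[str, Path]:
    """TSV (froi_i, froi_j, W, W_norm) + GraphML for one fROI network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for u, v, data in fnet.graph.edges(data=True):
        a, b = _ordered_edge(u, v)
        rows.append(
            {"froi_i": a, "froi_j": b, "W": data["W"], "W_norm": data.get("W_norm", float("nan"))}
        )
    df = pd.DataFrame(rows, columns=["froi_i", "froi_j", "W", "W_norm"]).sort_values(
        ["froi_i", "froi_j"], ignore_index=True
    )
    tsv_path = out_dir / f"{stem}_froi.tsv"
    gml_path = out_dir / f"{stem}_froi.graphml"
    df.to_csv(tsv_path, sep="\t", index=False)
    nx.write_graphml(fnet.graph, gml_path)
    return {"tsv": tsv_path, "graphml": gml_path}


def write_common_network(out_dir: str | Path, cnet: CommonNetwork, stem: str = "common") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{stem}.tsv"
    gml_path = out_dir / f"{stem}.graphml"
    cnet.to_frame().to_csv(tsv_path, sep="\t", index=False)
    nx.write_graphml(cnet.graph, gml_path)
    return {"tsv": tsv_path, "graphml": gml_path}


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters (YAML/JSON round-trippable)."""

    out_dir: str = "froinet_out"
    input_dir: str | None = None  # read subjects from here instead of simulating
    n_subjects: int = 20
    seed: int = 0
    theta: float = 0.7
    deltas: tuple[float, ...] = (-0.05, 0.05)
    p_thresh: float = 1e-4
    q_thresh: float = 1e-3
    presence_fraction: float = 0.85
    eq4_denominator: str = "possessors"
    n_bins: int = 10
    n_perm: int = 1000
    n_null: int = 50
    n_swaps: int | None = None
    exclude_frois: tuple[str, ...] = ()
    occupancy_frois: tuple[str, ...] | None = None  # default: common-network fROIs

    def __post_init__(self) -> None:
        for name in ("theta", "presence_fraction", "p_thresh", "q_thresh"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("n_subjects", "n_perm", "n_null", "n_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deltas"] = list(self.deltas)
        d["exclude_frois"] = list(self.exclude_frois)
        if self.occupancy_frois is not None:
            d["occupancy_frois"] = list(self.occupancy_frois)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "deltas" in d:
            d["deltas"] = tuple(d["deltas"])
        if "exclude_frois" in d:
            d["exclude_frois"] = tuple(d["exclude_frois"])
        if d.get("occupancy_frois") is not None:
            d["occupancy_frois"] = tuple(d["occupancy_frois"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PipelineConfig.from_dict(data or {})
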