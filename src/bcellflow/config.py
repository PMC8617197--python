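"""Run configuration: a nested-key YAML schema validated by pydantic.

Unknown keys are rejected; every stage owns a sub-model whose defaults match
the library functions. One global seed deterministically derives per-stage
seeds so stages can be rerun in isolation.
"""
from __future__ import annotations

import hashlib
import json
from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_cells: int = Field(2000, gt=0)
    n_genes: int = Field(1500, gt=0)
    n_stages: int = Field(6, gt=0)
    stage_props: Optional[List[float]] = None
    phase_props: Dict[str, float] = Field(
        default_factory=lambda: {"G0G1": 0.55, "S": 0.20, "G2M": 0.15, "G1PM": 0.10}
    )
    n_hashtags: int = 2
    doublet_rate: float = Field(0.10, ge=0, lt=1)
    n_adt: int = 6
    prog_genes_per_stage: int = 40
    n_gradient_genes: int = 30
    stage_lfc: float = 2.0
    phase_lfc: float = 2.0
    nb_dispersion: float = 10.0
    mito_gene_frac: float = 0.01
    continuous: bool = True


class DemuxSection(_Strict):
    k: Optional[int] = None  # default: n_hashtags + 1
    q: float = Field(0.99, gt=0.5, lt=1)
    k_scan: Optional[List[int]] = None


class FilterSection(_Strict):
    min_genes: int = 300
    min_cells: int = 3
    mito_top_frac: float = 0.005


class NormalizeSection(_Strict):
    method: str = "pearson_residual"
    theta: float = 100.0
    regress_mito: bool = True


class CellCycleSection(_Strict):
    n_bins: int = 24
    n_ctrl: int = 100
    raw_mean: bool = False


class ClusterSection(_Strict):
    n_pcs: int = Field(30, gt=0)
    scale_pca: bool = True
    knn_k: int = Field(20, gt=0)
    resolution: float = Field(0.4, gt=0)
    min_de: int = Field(5, ge=0)
    lfc: float = Field(0.25, ge=0)
    alpha: float = Field(0.01, gt=0, le=1)


class MarkersSection(_Strict):
    lfc: float = 0.25
    alpha: float = 0.01
    top_n: int = 25
    positive_only: bool = True


class TrajectorySection(_Strict):
    root_cluster: int = 0
    scale_pca: bool = False  # residuals are already variance-stabilised
    q_threshold: float = 0.05
    module_knn_k: int = 10
    module_resolution: float = 1.0


class EnrichSection(_Strict):
    n_subtypes: int = 4
    replicates_per_subtype: int = 3
    n_genes: int = 2000
    planted_lfc: float = 2.0
    min_genes: int = 3
    alpha: float = 0.05
    n_sim: int = Field(100, ge=20)
    min_n: int = Field(2, ge=2)


class StagesSection(_Strict):
    simulate: bool = True
    demux: bool = True
    cellcycle: bool = True
    cluster: bool = True
    markers: bool = True
    trajectory: bool = True
    enrich: bool = True


class RunConfig(_Strict):
    outdir: str = "bcellflow_run"
    seed: int = 0
    stages: StagesSection = Field(default_factory=StagesSection)
    sim: SimSection = Field(default_factory=SimSection)
    demux: DemuxSection = Field(default_factory=DemuxSection)
    filter: FilterSection = Field(default_factory=FilterSection)
    normalize: NormalizeSection = Field(default_factory=NormalizeSection)
    cellcycle: CellCycleSection = Field(default_factory=CellCycleSection)
    cluster: ClusterSection = Field(default_factory=ClusterSection)
    markers: MarkersSection = Field(default_factory=MarkersSection)
    trajectory: TrajectorySection = Field(default_factory=TrajectorySection)
    enrich: EnrichSection = Field(default_factory=EnrichSection)

    def stage_seed(self, stage: str) -> int:
        order = ["simulate", "demux", "cellcycle", "cluster", "markers", "trajectory", "enrich"]
        return (self.seed * 1000003 + order.index(stage) + 1) % (2**31)

    def config_hash(self) -> str:
        data = self.model_dump()
        data.pop("outdir", None)  # hash the analysis parameters, not the path
        payload = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)
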