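"""End-to-end orchestration: DE -> edge filter -> candidate pairs -> triads -> network.

`PipelineConfig` collects every threshold; the defaults are the canonical
analysis settings (fold change >= 2, FDR/p < 0.05, SCC < -0.7, PCC > 0.9,
pair p < 0.05, cis window 10 kb, trans |r| >= 0.95), so a bare run applies
the standard procedure to any input.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .core import ExpressionMatrix, TargetTable, ValidationError
from .de import call_de
from .filters import candidate_cerna_pairs, filter_mirna_targets
from .network import (
    CeRNANetwork,
    UNIVERSE_POLICIES,
    assemble_triads,
    build_network,
    mirna_universe,
    test_cerna_pairs,
)


@dataclass
class PipelineConfig:
    scc_cutoff: float = -0.7
    pcc_cutoff: float = 0.9
    pair_alpha: float = 0.05
    fc_min: float = 2.0
    de_fdr: float = 0.05
    mirna_de_p: float = 0.05
    cis_window: int = 10_000
    trans_r: float = 0.95
    pseudocount: float = 1e-2
    universe: str = "expressed"
    require_de: bool = True
    pearson_log2: bool = True
    top_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.scc_cutoff <= 0:
            raise ValidationError("scc_cutoff must lie in [-1, 0]")
        if not 0 <= self.pcc_cutoff <= 1:
            raise ValidationError("pcc_cutoff must lie in [0, 1]")
        for name in ("pair_alpha", "de_fdr", "mirna_de_p"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.fc_min < 1:
            raise ValidationError("fc_min must be >= 1")
        if self.cis_window < 0:
            raise ValidationError("cis_window must be >= 0")
        if not 0 <= self.trans_r <= 1:
            raise ValidationError("trans_r must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be > 0")
        if self.universe not in UNIVERSE_POLICIES:
            raise ValidationError(f"universe must be one of {UNIVERSE_POLICIES}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    de: pd.DataFrame
    edges: pd.DataFrame
    candidates: pd.DataFrame
    pair_tests: pd.DataFrame
    triads: pd.DataFrame
    network: CeRNANetwork


def run_pipeline(
    matrix: ExpressionMatrix,
    targets: TargetTable,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full ceRNA inference chain on in-memory inputs."""
    cfg = config or PipelineConfig()
    de = call_de(
        matrix,
        fc_min=cfg.fc_min,
        de_fdr=cfg.de_fdr,
        mirna_de_p=cfg.mirna_de_p,
        pseudocount=cfg.pseudocount,
    )
    edges = filter_mirna_targets(
        matrix, targets, de=de, scc_cutoff=cfg.scc_cutoff, require_de=cfg.require_de
    )
    candidates = candidate_cerna_pairs(
        matrix,
        edges,
        pcc_cutoff=cfg.pcc_cutoff,
        log2_scale=cfg.pearson_log2,
        pseudocount=cfg.pseudocount,
    )
    universe = mirna_universe(cfg.universe, matrix=matrix, edges=edges, de=de)
    pair_tests = test_cerna_pairs(candidates, edges, universe, alpha=cfg.pair_alpha)
    triads = assemble_triads(pair_tests, edges)
    net = build_network(triads)
    return PipelineResult(
        de=de, edges=edges, candidates=candidates, pair_tests=pair_tests, triads=triads, network=net
    )
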