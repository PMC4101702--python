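"""End-to-end convenience wrapper: expression + gene sets -> network."""

from __future__ import annotations

from dataclasses import dataclass

from .compression import CompressionParams, ProfileSet, build_plm
from .drivers import DrivingGeneReport, all_driving_genes
from .io import ExpressionMatrix, PathwayAnnotation
from .network import PathwayNetwork, build_network
from .rules import AssociationRule, infer_rules

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    profile_set: ProfileSet
    rules: list[AssociationRule]
    drivers: dict[str, DrivingGeneReport]
    network: PathwayNetwork


def run_pipeline(matrix: ExpressionMatrix, annotation: PathwayAnnotation,
                 params: CompressionParams | None = None,
                 accuracy_min: float = 0.9, dedupe: bool = False,
                 with_drivers: bool = True) -> PipelineResult:
    """Compress, infer rules, find driving genes and assemble the network."""
    params = params or CompressionParams()
    profile_set = build_plm(matrix, annotation, params)
    rules = infer_rules(profile_set, accuracy_min)
    drivers = all_driving_genes(profile_set) if with_drivers else {}
    provenance = {
        "alpha": params.alpha, "n_boot": params.n_boot,
        "q": params.q_threshold, "seed": params.seed,
        "accuracy_min": accuracy_min,
    }
    net = build_network(rules, profile_set, drivers or None,
                        dedupe=dedupe, params=provenance)
    return PipelineResult(profile_set, rules, drivers, net)
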