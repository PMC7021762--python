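"""Run configuration: the tunable parameters of the toolkit in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Defaults for solver, frailness and cohort analyses.

    ``epsilon = 1`` is the conventional fixed intensity for comparable
    frailness scores across query sets; pathway networks are kept between 10
    and 500 genes; the enrichment test draws the 10 least resilient samples
    from networks with at least 20 informative patients, and a marginal
    mutation is one in a degree-1 gene.
    """

    epsilon: float = 1.0
    norm: str = "operator"                  # operator | spectral | frobenius
    scheme_variant: str = "eq5b_consistent"  # | eq7b_literal
    rate: str = "per_node"                   # | shared
    scheme_tol: float = 1e-10
    scheme_max_iter: int = 10_000
    divergence_bound: float = 1e6
    bisection_tol_factor: float = 1e-6       # interval tolerance, in units of lambda_F
    kernel_tol: float = 1e-10
    min_size: int = 10
    max_size: int = 500
    top_n: int = 10
    min_patients: int = 20
    marginal_degree: int = 1
    seed: int = 0
    exclude: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("scheme_tol", "bisection_tol_factor", "kernel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_size > self.max_size:
            raise ValueError("min_size must not exceed max_size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True),
                              encoding="utf-8")

    def as_dict(self) -> dict:
        return asdict(self)
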