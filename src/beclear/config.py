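"""Run configuration: every tunable threshold and hyperparameter in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml


@dataclass
class RunConfig:
    """Defaults for the full detect -> score -> flag -> correct workflow.

    Detection: ``p_threshold`` (adjusted KS p), ``mdif_threshold`` (beta
    units, strict inequality), ``adjust_method`` in {fdr, bonferroni,
    hommel}.  Scoring: Dixon ``alpha``, ``score_floor`` (minimum BE-score a
    flagged batch must reach), ``weight_scheme`` in {doubling, linear}.
    Correction: latent rank ``r``, learning rate ``gamma``, L2 weight
    ``lambda_``, epoch cap ``epochs``, convergence ``tol``, block geometry.
    ``threads`` affects scheduling only, never numeric output.
    """

    p_threshold: float = 0.01
    mdif_threshold: float = 0.05
    adjust_method: str = "fdr"
    alpha: float = 0.01
    score_floor: float = 0.1
    weight_scheme: str = "doubling"
    iterate_flagging: bool = True
    r: int = 10
    gamma: float = 0.01
    lambda_: float = 0.01
    epochs: int = 200
    block_rows: int = 60
    block_cols: int = 60
    tol: float = 1e-6
    seed: int = 0
    threads: int = 1
    na_token: str = "NA"
    window_bp: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_dict(self) -> dict:
        return asdict(self)
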