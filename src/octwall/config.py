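"""Pipeline configuration.

The defaults are the method's reference operating point:
Gaussian scale sigma = 30 um, interface weights (0.2, 1, 1), minimal
contour gap 45 um, 2N+1 = 7 reachable neighbours, smoothness kappa = 0.1,
100 boosting rounds, morphological kernels K_E = 4 and K_D = 9, 100
angular steps over a 1 mm sub-image depth and a 300 um feature margin
below the AP contour.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .multilayer_dp import DPParams

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sigma_um: float = 30.0
    omega: tuple[float, float, float] = (0.2, 1.0, 1.0)
    kappa: float = 0.1
    N: int = 3
    gap_um: float = 45.0
    n_angles: int = 100
    depth_um: float = 1000.0
    margin_um: float = 300.0
    n_rounds: int = 100
    K_E: int = 4
    K_D: int = 9
    features: str = "relevant8"  # or "all17"
    downsample: int | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        self.omega = tuple(self.omega)
        if self.features not in ("relevant8", "all17"):
            raise ValueError("features must be 'relevant8' or 'all17'")

    def dp_params(self) -> DPParams:
        return DPParams(omega=self.omega, kappa=self.kappa, N=self.N,
                        gap_um=self.gap_um)

    def active_features(self) -> list[str]:
        from .wall_features import FEATURE_NAMES, RELEVANT_FEATURES
        return list(RELEVANT_FEATURES if self.features == "relevant8"
                    else FEATURE_NAMES)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["omega"] = list(d["omega"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
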