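"""Declarative scenario configuration (YAML) with a strict schema.

A scenario bundles everything needed to design a trial: the outcome model,
the hypothesis thresholds, named analysis priors, a sampling prior (or a grid
of them for sensitivity scans), cost parameters or goal targets, Phase III
settings, and numerical knobs.  Unknown keys are rejected.  Two fixtures ship
with the package: ``normal_conjugate`` (a normal-outcome simulation scenario
with vague / informative / robust-mixture / EB-power analysis priors) and
``binomial_poc`` (a single-arm binomial proof-of-concept trial).
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import models as md
from .conditional import Phase3Spec
from .decisions import CostSpec, Hypotheses

__all__ = ["ScenarioConfig", "load_config", "load_fixture", "fixture_names",
           "config_hash", "build_prior", "build_sampling_prior"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelBlock(_Strict):
    family: Literal["normal_known_variance", "binomial"]
    sigma2: Optional[float] = None


class HypothesesBlock(_Strict):
    theta0: float
    thetaR: float


class HistoricalBlock(_Strict):
    n0: int
    mean: Optional[float] = None
    successes: Optional[int] = None
    failures: Optional[int] = None

    @model_validator(mode="after")
    def _one_summary(self):
        has_mean = self.mean is not None
        has_counts = self.successes is not None and self.failures is not None
        if has_mean == has_counts:
            raise ValueError("give either a historical mean or success/failure counts")
        return self


class PriorBlock(_Strict):
    kind: Literal["normal", "beta", "point_mass", "mixture", "power"]
    mean: Optional[float] = None
    variance: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    location: Optional[float] = None
    components: Optional[list["PriorBlock"]] = None
    weights: Optional[list[float]] = None
    historical: Optional[HistoricalBlock] = None
    baseline: Optional["PriorBlock"] = None
    a0: Optional[Union[float, Literal["empirical_bayes"]]] = None


class GridBlock(_Strict):
    """Sampling-prior grid: normal grids share a variance across means; beta
    grids share the prior strength a+b."""

    kind: Literal["normal", "beta", "point_mass"]
    means: list[float]
    variance: Optional[float] = None
    strength: Optional[float] = None


class SamplingBlock(_Strict):
    prior: PriorBlock
    truncation: Optional[tuple[float, float]] = None
    grid: Optional[GridBlock] = None


class CostsBlock(_Strict):
    c0p: float = 0.05
    c1p: float = 0.95
    mode: Literal["bf_reweighted", "plain"] = "bf_reweighted"


class GoalsBlock(_Strict):
    n_sate: Optional[int] = None
    n_amse: Optional[int] = None
    type1_max: Optional[float] = None
    type2_max: Optional[float] = None
    sate_max: Optional[float] = None
    amse_max: Optional[float] = None
    indeterminate_max: Optional[float] = None
    power_loss_max: Optional[float] = None
    n_gain_max: Optional[float] = None


class Phase3Block(_Strict):
    target_power: float = 0.9
    alpha3: float = 0.025
    zeta: float = 0.2
    n_cap: float = 1e6


class NGridBlock(_Strict):
    start: int = 1
    stop: int = 150
    step: int = 1


class SmoothingBlock(_Strict):
    smooth_sate: bool = False
    smooth_amse: bool = False
    bandwidth_sate: int = 101
    bandwidth_amse: int = 15


class NumericsBlock(_Strict):
    n_grid: NGridBlock = Field(default_factory=NGridBlock)
    theta_order: int = 199
    gh_order: int = 199
    scan_points: int = 1601
    smoothing: SmoothingBlock = Field(default_factory=SmoothingBlock)
    eval_n: Optional[int] = None
    seed: int = 0


class OutputBlock(_Strict):
    directory: str = "results"
    formats: list[Literal["csv", "json"]] = Field(default_factory=lambda: ["csv", "json"])


class ScenarioConfig(_Strict):
    name: str = "scenario"
    model: ModelBlock
    hypotheses: HypothesesBlock
    analysis_priors: dict[str, PriorBlock]
    sampling: SamplingBlock
    costs: CostsBlock = Field(default_factory=CostsBlock)
    goals: Optional[GoalsBlock] = None
    phase3: Phase3Block = Field(default_factory=Phase3Block)
    numerics: NumericsBlock = Field(default_factory=NumericsBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    # ---- conversion to runtime objects -------------------------------

    def trial_model(self) -> md.TrialModel:
        return md.TrialModel(self.model.family, self.model.sigma2)

    def hyp(self) -> Hypotheses:
        return Hypotheses(self.hypotheses.theta0, self.hypotheses.thetaR)

    def cost_spec(self) -> CostSpec:
        return CostSpec(self.costs.c0p, self.costs.c1p, self.costs.mode)

    def phase3_spec(self) -> Phase3Spec:
        p = self.phase3
        return Phase3Spec(p.target_power, p.alpha3, p.zeta, p.n_cap)

    def priors(self) -> dict[str, md.AnalysisPrior]:
        return {name: build_prior(p) for name, p in self.analysis_priors.items()}

    def sampling_prior(self) -> md.SamplingPrior:
        return build_sampling_prior(self.sampling)

    def sampling_grid(self) -> tuple[list[md.SamplingPrior], list[float]]:
        g = self.sampling.grid
        if g is None:
            raise ValueError("no sampling-prior grid in this scenario")
        priors, labels = [], []
        for m in g.means:
            if g.kind == "normal":
                if g.variance is None:
                    raise ValueError("normal sampling grid needs a variance")
                priors.append(md.SamplingPrior(md.NormalPrior(m, g.variance)))
            elif g.kind == "beta":
                if g.strength is None:
                    raise ValueError("beta sampling grid needs a strength a+b")
                priors.append(md.SamplingPrior(
                    md.BetaPrior(m * g.strength, (1 - m) * g.strength)))
            else:
                priors.append(md.SamplingPrior(md.PointMassPrior(m)))
            labels.append(m)
        return priors, labels

    def n_grid(self) -> np.ndarray:
        g = self.numerics.n_grid
        return np.arange(g.start, g.stop + 1, g.step)


def build_prior(block: PriorBlock) -> md.AnalysisPrior:
    k = block.kind
    if k == "normal":
        return md.NormalPrior(block.mean, block.variance)
    if k == "beta":
        return md.BetaPrior(block.a, block.b)
    if k == "point_mass":
        return md.PointMassPrior(block.location)
    if k == "mixture":
        comps = tuple(build_prior(c) for c in block.components)
        return md.MixturePrior(comps, tuple(block.weights))
    hist = block.historical
    if hist.mean is not None:
        historical = md.HistoricalData(hist.n0, hist.mean)
    else:
        historical = md.HistoricalData(hist.n0, (hist.successes, hist.failures))
    a0 = block.a0 if block.a0 is not None else md.EMPIRICAL_BAYES
    return md.PowerPrior(historical, build_prior(block.baseline), a0)


def build_sampling_prior(block: SamplingBlock) -> md.SamplingPrior:
    return md.SamplingPrior(build_prior(block.prior), block.truncation)


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse and validate a scenario file; schema violations are itemized."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: not a mapping (empty or malformed config)")
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as err:
        lines = [f"invalid scenario config {path}:"]
        for e in err.errors():
            loc = ".".join(str(p) for p in e["loc"])
            lines.append(f"  - {loc}: {e['msg']}")
        raise ValueError("\n".join(lines)) from None


def fixture_names() -> list[str]:
    root = resources.files("bdtdesign") / "fixtures"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_fixture(name: str) -> ScenarioConfig:
    """Load a built-in scenario by name (see :func:`fixture_names`)."""
    path = resources.files("bdtdesign") / "fixtures" / f"{name}.yaml"
    if not path.is_file():
        raise ValueError(f"unknown fixture {name!r}; available: {fixture_names()}")
    raw = yaml.safe_load(path.read_text())
    return ScenarioConfig.model_validate(raw)


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable digest of the resolved configuration, for output provenance."""
    blob = yaml.safe_dump(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
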