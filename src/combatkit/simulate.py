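"""Synthetic feature tables with known batch, hidden-group and covariate structure.

The generator emulates the statistical structure of multi-site radiomic
feature tables: per-feature additive (location) and multiplicative (scale)
batch effects for one or more categorical acquisition variables, a hidden
binary variable inducing bimodal feature distributions, and protected
clinical-covariate effects, on top of i.i.d. Gaussian noise. Feature
baselines are standardized (zero mean, ``noise_sd`` scale) so all effect
sizes are interpretable in SD units. Every draw is reproducible from the
spec's mandatory seed, and the full ground truth (labels, affected features,
true shift/scale values) is returned for oracle checks.

Per sample j and feature g the generative model is

    Y_jg = sum_e loc_e[label_e(j), g]  +  (prod_e scale_e[label_e(j), g]) * eps_jg
           + hidden_shift_g * 1[hidden(j) = 1] + sum_c cov_effect_cg * x_cj

with ``eps ~ N(0, noise_sd^2)``, i.e. batch scale acts on the noise term
exactly as the location/scale harmonization model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchEffectSpec",
    "HiddenGroupSpec",
    "CovariateSpec",
    "SimulationSpec",
    "GroundTruth",
    "SimulatedData",
    "simulate",
    "lung3_like_spec",
]


def _check_proportions(props: tuple[float, ...], what: str) -> None:
    if len(props) < 2:
        raise ValueError(f"{what}: need at least two level proportions")
    if any(not 0 < p < 1 for p in props):
        raise ValueError(f"{what}: proportions must lie strictly in (0, 1), got {props}")
    if abs(sum(props) - 1.0) > 1e-8:
        raise ValueError(f"{what}: proportions must sum to 1, got {props}")


def _exact_counts(props: tuple[float, ...], n: int) -> np.ndarray:
    """Largest-remainder apportionment of n samples to level proportions."""
    raw = np.asarray(props) * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n - counts.sum()]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class BatchEffectSpec:
    """One categorical batch effect.

    ``location_sd`` is the SD of the per-level, per-feature additive shifts
    (drawn N(0, location_sd^2), centered so the sample-size-weighted shift is
    zero per feature); ``scale_range`` bounds the per-level multiplicative
    noise-scale factors (uniform); ``affected_fraction`` is the share of
    features carrying this effect.
    """

    name: str
    proportions: tuple[float, ...] = (0.5, 0.5)
    location_sd: float = 1.0
    scale_range: tuple[float, float] = (1.0, 1.0)
    affected_fraction: float = 1.0
    levels: tuple[str, ...] | None = None

    def level_names(self) -> tuple[str, ...]:
        if self.levels is not None:
            if len(self.levels) != len(self.proportions):
                raise ValueError(f"batch effect {self.name!r}: levels/proportions mismatch")
            return self.levels
        return tuple(f"{self.name}{i}" for i in range(len(self.proportions)))


@dataclass(frozen=True)
class HiddenGroupSpec:
    """A latent binary variable inducing bimodality.

    ``separation`` is the between-group mean difference in units of
    ``noise_sd`` on the affected ("bimodal") features; the variable is NOT
    written to the metadata table — it lives only in the ground truth.
    """

    fraction_bimodal: float = 0.3
    separation: float = 4.0
    proportions: tuple[float, float] = (0.5, 0.5)


@dataclass(frozen=True)
class CovariateSpec:
    """A protected clinical covariate with a true effect on some features.

    ``kind`` is ``"binary"`` (categorical, levels drawn by ``proportions``)
    or ``"continuous"`` (standard normal values). ``effect_size`` is in
    noise-SD units per level change / per unit of the continuous value.
    """

    name: str
    kind: str = "binary"
    effect_size: float = 1.0
    affected_fraction: float = 1.0
    proportions: tuple[float, float] = (0.5, 0.5)


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic dataset; ``seed`` is mandatory."""

    n_samples: int = 85
    n_features: int = 100
    batch_effects: tuple[BatchEffectSpec, ...] = ()
    hidden: HiddenGroupSpec | None = None
    covariates: tuple[CovariateSpec, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4 or self.n_features < 1:
            raise ValueError("need n_samples >= 4 and n_features >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        names = [b.name for b in self.batch_effects]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate batch-effect names: {names}")
        for b in self.batch_effects:
            _check_proportions(b.proportions, f"batch effect {b.name!r}")
            if not 0 <= b.affected_fraction <= 1:
                raise ValueError(f"batch effect {b.name!r}: affected_fraction outside [0, 1]")
            if b.scale_range[0] <= 0 or b.scale_range[1] < b.scale_range[0]:
                raise ValueError(f"batch effect {b.name!r}: invalid scale_range {b.scale_range}")
            counts = _exact_counts(b.proportions, self.n_samples)
            if counts.min() < 2:
                raise ValueError(
                    f"batch effect {b.name!r}: a level would receive {counts.min()} "
                    f"sample(s) at n={self.n_samples}; at least 2 are required"
                )
        if self.hidden is not None:
            h = self.hidden
            _check_proportions(h.proportions, "hidden group")
            if not 0 <= h.fraction_bimodal <= 1 or h.separation < 0:
                raise ValueError("hidden group: fraction in [0,1] and separation >= 0 required")
        for c in self.covariates:
            if c.kind not in ("binary", "continuous"):
                raise ValueError(f"covariate {c.name!r}: kind must be binary or continuous")
            if c.kind == "binary":
                _check_proportions(c.proportions, f"covariate {c.name!r}")


@dataclass
class GroundTruth:
    """Everything an oracle needs: labels, affected features, true effects."""

    batch_labels: pd.DataFrame
    hidden_labels: pd.Series | None
    covariate_values: pd.DataFrame
    batch_affected: dict[str, pd.Series] = field(default_factory=dict)
    batch_location: dict[str, pd.DataFrame] = field(default_factory=dict)
    batch_scale: dict[str, pd.DataFrame] = field(default_factory=dict)
    bimodal_features: pd.Series | None = None
    hidden_shift: pd.Series | None = None
    covariate_effects: dict[str, pd.Series] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {
            "batch_labels": {c: self.batch_labels[c].to_dict() for c in self.batch_labels},
            "covariate_values": {
                c: self.covariate_values[c].to_dict() for c in self.covariate_values
            },
            "batch_affected": {k: v[v].index.tolist() for k, v in self.batch_affected.items()},
            "batch_location": {k: v.to_dict() for k, v in self.batch_location.items()},
            "batch_scale": {k: v.to_dict() for k, v in self.batch_scale.items()},
            "covariate_effects": {k: v.to_dict() for k, v in self.covariate_effects.items()},
        }
        if self.hidden_labels is not None:
            out["hidden_labels"] = self.hidden_labels.to_dict()
            out["bimodal_features"] = self.bimodal_features[self.bimodal_features].index.tolist()
            out["hidden_shift"] = self.hidden_shift.to_dict()
        return out


@dataclass
class SimulatedData:
    features: pd.DataFrame
    metadata: pd.DataFrame
    truth: GroundTruth
    spec: SimulationSpec


def _assign_levels(
    rng: np.random.Generator, n: int, props: tuple[float, ...], names: tuple[str, ...]
) -> np.ndarray:
    counts = _exact_counts(props, n)
    labels = np.repeat(np.asarray(names, dtype=object), counts)
    return labels[rng.permutation(n)]


def simulate(spec: SimulationSpec) -> SimulatedData:
    """Draw one dataset from the spec; byte-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_samples, spec.n_features
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    feature_names = pd.Index([f"feat_{j:03d}" for j in range(g)])

    eps = rng.normal(0.0, spec.noise_sd, size=(n, g))
    loc_total = np.zeros((n, g))
    scale_total = np.ones((n, g))
    meta = pd.DataFrame(index=sample_ids)
    truth = GroundTruth(
        batch_labels=pd.DataFrame(index=sample_ids),
        hidden_labels=None,
        covariate_values=pd.DataFrame(index=sample_ids),
    )

    for b in spec.batch_effects:
        level_names = b.level_names()
        labels = _assign_levels(rng, n, b.proportions, level_names)
        meta[b.name] = labels
        truth.batch_labels[b.name] = labels
        n_aff = int(round(b.affected_fraction * g))
        affected_idx = rng.choice(g, size=n_aff, replace=False)
        affected = np.zeros(g, dtype=bool)
        affected[affected_idx] = True

        shifts = np.zeros((len(level_names), g))
        shifts[:, affected] = rng.normal(0.0, b.location_sd, size=(len(level_names), n_aff))
        counts = pd.Series(labels).value_counts().reindex(level_names).to_numpy()
        shifts -= (counts / n) @ shifts  # weighted centering: identifiable truth
        scales = np.ones((len(level_names), g))
        if b.scale_range != (1.0, 1.0):
            scales[:, affected] = rng.uniform(
                b.scale_range[0], b.scale_range[1], size=(len(level_names), n_aff)
            )
        code = pd.Categorical(labels, categories=level_names).codes
        loc_total += shifts[code]
        scale_total *= scales[code]
        truth.batch_affected[b.name] = pd.Series(affected, index=feature_names)
        truth.batch_location[b.name] = pd.DataFrame(
            shifts, index=list(level_names), columns=feature_names
        )
        truth.batch_scale[b.name] = pd.DataFrame(
            scales, index=list(level_names), columns=feature_names
        )

    hidden_part = np.zeros((n, g))
    if spec.hidden is not None:
        h = spec.hidden
        hidden = _assign_levels(rng, n, h.proportions, ("0", "1"))
        n_bi = int(round(h.fraction_bimodal * g))
        bi_idx = rng.choice(g, size=n_bi, replace=False)
        bimodal = np.zeros(g, dtype=bool)
        bimodal[bi_idx] = True
        shift = np.zeros(g)
        shift[bimodal] = h.separation * spec.noise_sd
        hidden_part = (hidden == "1")[:, None] * shift[None, :]
        truth.hidden_labels = pd.Series(hidden, index=sample_ids, name="hidden")
        truth.bimodal_features = pd.Series(bimodal, index=feature_names)
        truth.hidden_shift = pd.Series(shift, index=feature_names)

    cov_part = np.zeros((n, g))
    for c in spec.covariates:
        if c.kind == "binary":
            values = _assign_levels(rng, n, c.proportions, ("ctrl", "case"))
            numeric = (values == "case").astype(float)
        else:
            numeric = rng.normal(0.0, 1.0, size=n)
            values = numeric
        meta[c.name] = values
        truth.covariate_values[c.name] = values
        n_aff = int(round(c.affected_fraction * g))
        aff_idx = rng.choice(g, size=n_aff, replace=False)
        effect = np.zeros(g)
        effect[aff_idx] = c.effect_size * spec.noise_sd
        cov_part += np.asarray(numeric, dtype=float)[:, None] * effect[None, :]
        truth.covariate_effects[c.name] = pd.Series(effect, index=feature_names)

    values = loc_total + scale_total * eps + hidden_part + cov_part
    features = pd.DataFrame(values, index=sample_ids, columns=feature_names)
    return SimulatedData(features=features, metadata=meta, truth=truth, spec=spec)


def lung3_like_spec(seed: int, **overrides) -> SimulationSpec:
    """Default desk-scale fixture: 85 samples x 100 features, three two-level
    batch effects with level proportions mirroring a typical multi-site lung
    CT cohort (contrast enhancement 40/60, spatial resolution 58/42,
    manufacturer 44/56), moderate location/scale effects, and one protected
    binary covariate."""
    base = dict(
        n_samples=85,
        n_features=100,
        batch_effects=(
            BatchEffectSpec(
                "ce", proportions=(0.4, 0.6), location_sd=1.0,
                scale_range=(0.8, 1.25), affected_fraction=0.8,
                levels=("nCE", "CE"),
            ),
            BatchEffectSpec(
                "resolution", proportions=(0.58, 0.42), location_sd=0.5,
                scale_range=(0.9, 1.1), affected_fraction=0.6,
                levels=("low", "high"),
            ),
            BatchEffectSpec(
                "manufacturer", proportions=(0.44, 0.56), location_sd=0.25,
                scale_range=(1.0, 1.0), affected_fraction=0.5,
                levels=("siemens", "philips"),
            ),
        ),
        covariates=(CovariateSpec("histology", kind="binary", effect_size=1.0,
                                  affected_fraction=0.5),),
        noise_sd=1.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationSpec(**base)
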