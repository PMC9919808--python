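"""Canonical study protocols: scripts, regimes and the model comparison.

Two named simulation regimes recur throughout the package:

* the **separable regime** — low sensor noise, no spikes, involuntary
  micro-movements scripted out and a pronounced coughing fit, so that the
  five activities are per-sample separable.  Used to verify that the
  end-to-end pipeline recovers a scripted activity sequence;
* the **confusable benchmark** (see
  :func:`harcascade.simulate.make_confusable_benchmark`) — the default
  noisy regime with overlapping postures, used for the regular-vs-cascade
  comparison.

The regular-vs-cascade comparison mirrors how such systems are validated
in practice: both models are trained on one recording session and
evaluated on an independently generated session (fresh posture draws,
fresh noise), not on a within-session split — within-session splits place
near-duplicate neighbouring samples on both sides and mask the
generalisation differences the comparison is about.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import ClassifierSpec, predict_flat, predict_ptle, train_flat, train_ptle
from .features import feature_table
from .simulate import ActivityScriptSegment, SimConfig, make_confusable_benchmark

__all__ = [
    "SEPARABLE_OVERRIDES",
    "separable_config",
    "separable_training_script",
    "demo_scenario",
    "ComparisonResult",
    "compare_regular_vs_cascade",
]

#: Per-activity overrides defining the separable regime: static activities
#: are truly static, and a coughing fit is pronounced (strong respiratory
#: effort, more than one cough per second).
SEPARABLE_OVERRIDES: dict[str, dict[str, float]] = {
    "sit": {"fidget_rate_hz": 0.0},
    "sleep": {"turnover_rate_hz": 0.0},
    "cough": {"effort_amp_g": 0.45, "burst_rate_hz": 1.2},
}


def separable_config(seed: int) -> SimConfig:
    return SimConfig(noise_sd_g=0.02, spike_prob=0.0, seed=seed)


def _seg(activity: str, duration_s: float) -> ActivityScriptSegment:
    return ActivityScriptSegment(
        activity, duration_s, SEPARABLE_OVERRIDES.get(activity, {})
    )


def separable_training_script(reps: int = 20) -> list[ActivityScriptSegment]:
    """Training script for the separable regime.

    Many short segments rather than a few long ones, so the training data
    covers a spread of per-segment posture draws for every activity.
    """
    script: list[ActivityScriptSegment] = []
    for _ in range(reps):
        for activity in ("sit", "walk", "sleep", "cough"):
            script.append(_seg(activity, 4.0))
        script.append(_seg("fall", 2.0))
    return script


def demo_scenario() -> list[ActivityScriptSegment]:
    """A monitored hour-in-miniature: routine activity, one coughing fit,
    one fall."""
    return [
        _seg("sit", 15.0),
        _seg("walk", 15.0),
        _seg("cough", 5.0),
        _seg("sleep", 15.0),
        _seg("fall", 2.0),
        _seg("sit", 8.0),
    ]


@dataclass(frozen=True)
class ComparisonResult:
    """Cross-session accuracies of the cascade and the flat baseline."""

    ptle_accuracies: tuple[float, ...]
    flat_accuracies: tuple[float, ...]
    seeds: tuple[int, ...]
    n_train: int
    n_test: int

    @property
    def mean_ptle(self) -> float:
        return float(np.mean(self.ptle_accuracies))

    @property
    def mean_flat(self) -> float:
        return float(np.mean(self.flat_accuracies))

    @property
    def advantage(self) -> float:
        """Mean accuracy difference, cascade minus flat."""
        return self.mean_ptle - self.mean_flat


def compare_regular_vs_cascade(
    seeds=range(5),
    n_train_per_class: int = 500,
    n_test_per_class: int = 300,
    config: SimConfig | None = None,
) -> ComparisonResult:
    """Replicate-averaged comparison of the cascade against the flat model.

    For each seed, both models are trained on one confusable benchmark
    session and evaluated on an independent session (seed offset by 1000);
    replicate accuracies are averaged over seeds.  Each replicate uses the
    default random-forest specification for every model slot.
    """
    ptle_accs: list[float] = []
    flat_accs: list[float] = []
    seeds = tuple(int(s) for s in seeds)
    for seed in seeds:
        train_cfg = config if config is not None else SimConfig(seed=seed)
        test_cfg = SimConfig(
            sampling_rate_hz=train_cfg.sampling_rate_hz,
            accel_range_g=train_cfg.accel_range_g,
            noise_sd_g=train_cfg.noise_sd_g,
            spike_prob=train_cfg.spike_prob,
            spike_magnitude_g=train_cfg.spike_magnitude_g,
            seed=seed + 1000,
        )
        train = feature_table(
            make_confusable_benchmark(train_cfg, n_train_per_class, seed=seed)
        )
        test = feature_table(
            make_confusable_benchmark(test_cfg, n_test_per_class, seed=seed + 1000)
        )
        y = test["label"].to_numpy()
        cascade = train_ptle(train, specs=ClassifierSpec("RF", seed=seed))
        flat = train_flat(train, spec=ClassifierSpec("RF", seed=seed))
        ptle_accs.append(float(np.mean(predict_ptle(cascade, test) == y)))
        flat_accs.append(float(np.mean(predict_flat(flat, test) == y)))
    return ComparisonResult(
        tuple(ptle_accs),
        tuple(flat_accs),
        seeds,
        n_train=5 * n_train_per_class,
        n_test=5 * n_test_per_class,
    )
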