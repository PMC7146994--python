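"""Online statistical quality control of a generator during training.

After every training epoch an independent examiner draws a sample of
generated strings, measures the fraction that are valid SMILES, and
compares it against binomial confidence-interval control margins around
a target rate. A run of ``patience`` consecutive in-control epochs
stops training, and the first epoch of that run — the earliest stable
model — is selected. The examiner never feeds back into the learning
process; it only observes and stops.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import Vocabulary


@dataclass(frozen=True)
class SQCConfig:
    """Examiner parameters.

    ``population_size`` enables the finite population correction; when
    omitted the population is treated as effectively infinite. With
    ``two_sided`` the streak also resets when validity exceeds the
    upper margin; by default only dropping below the lower margin
    resets (above-target validity is desirable).
    """

    target_rate: float = 0.97
    sample_size: int = 300
    population_size: Optional[int] = None
    confidence: float = 0.95
    patience: int = 10
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_rate <= 1.0:
            raise ValueError("target_rate must be in [0, 1]")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if (
            self.population_size is not None
            and self.population_size < self.sample_size
        ):
            raise ValueError("population_size must be >= sample_size")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    validity: float  # percent
    below_lower: bool
    streak_length_after: int


@dataclass
class ExaminationResult:
    stopped_epoch: int
    selected_epoch: int
    records: list[EpochRecord]
    lower_margin: float  # percent
    upper_margin: float  # percent
    converged: bool


def ci_margins(
    config: SQCConfig, method: str = "normal"
) -> tuple[float, float]:
    """Control margins (as fractions) around the target rate.

    ``normal`` uses the normal approximation p ± z·sqrt(p(1−p)/n),
    shrunk by the finite population correction when a population size
    is given, clamped to [0, 1]. ``exact`` uses the discrete binomial
    quantiles of the sample proportion instead. Degenerate targets 0
    and 1 produce zero-width margins with a warning.
    """
    p, n = config.target_rate, config.sample_size
    if p in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate target rate: zero-width margins")
        return p, p
    if method == "normal":
        z = stats.norm.ppf(0.5 + config.confidence / 2.0)
        half = z * np.sqrt(p * (1.0 - p) / n)
        if config.population_size is not None:
            N = config.population_size
            fpc = np.sqrt((N - n) / (N - 1)) if N > 1 else 0.0
            half *= fpc
        return max(0.0, p - half), min(1.0, p + half)
    if method == "exact":
        # exact quantiles of the sample proportion X/n, X ~ Binom(n, p):
        # the range the measured validity stays inside with the stated
        # confidence when the generator truly runs at the target rate
        alpha = 1.0 - config.confidence
        lower = stats.binom.ppf(alpha / 2.0, n, p) / n
        upper = stats.binom.ppf(1.0 - alpha / 2.0, n, p) / n
        return float(lower), float(upper)
    raise ValueError(f"unknown CI method {method!r}")


def update_streak(
    validity_percent: float,
    lower_percent: float,
    prior_streak: int,
    upper_percent: Optional[float] = None,
) -> int:
    """One transition of the stability counter. The streak resets when
    validity falls strictly below the lower margin (and, in two-sided
    mode, when it exceeds the upper margin); otherwise it increments."""
    if validity_percent < lower_percent:
        return 0
    if upper_percent is not None and validity_percent > upper_percent:
        return 0
    return prior_streak + 1


def examine_epoch(
    sampler: Callable[[int, int], Sequence[str]],
    config: SQCConfig,
    prior_streak: int,
    seed: int,
    epoch: int = 0,
) -> EpochRecord:
    """Draw one examination sample and update the stability streak.

    ``sampler(n, seed)`` must return n candidate SMILES strings.
    Validity is measured by the same checker used in final evaluation;
    strings with easily detected ring/branch mismatches count as
    invalid and stay in the denominator.
    """
    from .metrics import validity_percent as measure

    strings = sampler(config.sample_size, seed)
    validity = measure(strings)
    lower, upper = ci_margins(config)
    streak = update_streak(
        validity,
        lower * 100.0,
        prior_streak,
        upper * 100.0 if config.two_sided else None,
    )
    return EpochRecord(
        epoch=epoch,
        validity=validity,
        below_lower=validity < lower * 100.0,
        streak_length_after=streak,
    )


def run_examination(
    validities: Iterable[float],
    config: SQCConfig,
) -> ExaminationResult:
    """Replay the stopping automaton over a stream of per-epoch
    validity percentages.

    Stops at the first epoch whose streak reaches ``patience`` and
    selects the first epoch of that streak. If the stream ends first,
    the result is flagged non-converged and the first epoch of the
    terminal streak is selected (falling back to the highest-validity
    epoch when the final epoch itself was out of control).
    """
    lower, upper = ci_margins(config)
    lower_pct, upper_pct = lower * 100.0, upper * 100.0
    records: list[EpochRecord] = []
    streak = 0
    for epoch, validity in enumerate(validities, start=1):
        streak = update_streak(
            validity,
            lower_pct,
            streak,
            upper_pct if config.two_sided else None,
        )
        records.append(
            EpochRecord(
                epoch=epoch,
                validity=validity,
                below_lower=validity < lower_pct,
                streak_length_after=streak,
            )
        )
        if streak >= config.patience:
            return ExaminationResult(
                stopped_epoch=epoch,
                selected_epoch=epoch - config.patience + 1,
                records=records,
                lower_margin=lower_pct,
                upper_margin=upper_pct,
                converged=True,
            )
    if not records:
        raise ValueError("empty validity stream")
    last = records[-1]
    if last.streak_length_after > 0:
        selected = last.epoch - last.streak_length_after + 1
    else:
        selected = max(records, key=lambda r: r.validity).epoch
    return ExaminationResult(
        stopped_epoch=last.epoch,
        selected_epoch=selected,
        records=records,
        lower_margin=lower_pct,
        upper_margin=upper_pct,
        converged=False,
    )


class Examiner:
    """Stateful per-epoch examiner usable as a training callback.

    Wraps the streak automaton around live generation: at each epoch it
    samples ``config.sample_size`` strings from the model (with a seed
    derived from (run_seed, epoch) so reruns reproduce), measures
    validity and signals stop when the streak reaches patience.
    """

    def __init__(
        self,
        config: SQCConfig,
        vocab: Vocabulary,
        run_seed: int = 0,
        temperature: float = 1.0,
        max_length: int = 120,
    ) -> None:
        self.config = config
        self.vocab = vocab
        self.run_seed = run_seed
        self.temperature = temperature
        self.max_length = max_length
        self.records: list[EpochRecord] = []
        self._streak = 0
        lower, upper = ci_margins(config)
        self.lower_margin = lower * 100.0
        self.upper_margin = upper * 100.0

    def __call__(self, epoch: int, model) -> tuple[bool, float]:
        from .model import generate_smiles

        def sampler(n: int, seed: int) -> Sequence[str]:
            return generate_smiles(
                model,
                self.vocab,
                n,
                temperature=self.temperature,
                max_length=self.max_length,
                seed=seed,
            ).strings

        seed = int(
            np.random.default_rng((self.run_seed, epoch)).integers(2**31)
        )
        record = examine_epoch(
            sampler, self.config, self._streak, seed, epoch=epoch
        )
        self._streak = record.streak_length_after
        self.records.append(record)
        stop = self._streak >= self.config.patience
        return stop, record.validity

    def result(self) -> ExaminationResult:
        return run_examination(
            [r.validity for r in self.records], self.config
        )

    def write_log(self, path: Path) -> None:
        result = self.result()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                [
                    "epoch",
                    "validity_percent",
                    "lower_margin",
                    "upper_margin",
                    "streak",
                    "stopped",
                    "selected",
                ]
            )
            for r in self.records:
                writer.writerow(
                    [
                        r.epoch,
                        f"{r.validity:.4f}",
                        f"{self.lower_margin:.4f}",
                        f"{self.upper_margin:.4f}",
                        r.streak_length_after,
                        int(r.epoch == result.stopped_epoch),
                        int(r.epoch == result.selected_epoch),
                    ]
                )
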