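"""Synthetic predictor ensembles with controlled accuracy and correlation.

The simulator stands in for running real variant-effect predictors: it
generates labeled mutation datasets and, for each simulated tool, class
calls with raw confidences whose relationship to correctness is known by
construction.  That makes every downstream stage — calibration fitting,
consensus voting, evaluation — testable against analytically known truth.

Per tool, a confidence c is drawn from the true-class confidence
distribution and the call is correct with probability a(c), the tool's
accuracy curve.  Inter-tool correlation comes from a shared per-mutation
latent difficulty: with probability rho a tool thresholds the shared
uniform draw instead of its own, which preserves each tool's marginal
accuracy exactly for any rho and makes tools conditionally independent at
rho = 0.

The generator's defaults emulate the regime of a six-tool ensemble of
established predictors: marginal accuracies between 0.65 and 0.75,
informative confidences for most tools, per-tool missingness between 0 and
0.4, and a balanced neutral/deleterious benchmark.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .records import (
    AMINO_ACIDS,
    CATEGORICAL,
    CONTINUOUS,
    DELETERIOUS,
    MISSING,
    NEUTRAL,
    MutationRecord,
    ToolPrediction,
)

#: Background amino-acid frequencies of a large non-redundant protein
#: database (order matches AMINO_ACIDS = alphabetical one-letter codes).
BACKGROUND_AA_FREQS: dict[str, float] = dict(
    zip(
        AMINO_ACIDS,
        (
            lambda v: v / v.sum()
        )(
            np.array(
                [
                    8.26, 1.37, 5.46, 6.72, 3.86, 7.08, 2.27, 5.93, 5.80,
                    9.65, 2.41, 4.06, 4.73, 3.93, 5.53, 6.60, 5.35, 6.86,
                    1.09, 2.92,
                ]
            )
        ),
    )
)


@dataclass(frozen=True)
class ToolProfile:
    """Generative description of one simulated predictor.

    accuracy_curve: ("constant", a) | ("identity",) with P(correct|c) = c |
    ("logistic", slope, midpoint) with P(correct|c) = 1/(1+exp(-slope*(c-mid))).
    confidence: ("uniform", lo, hi) | ("beta", alpha, beta), drawn per
    mutation; the same family is used for both true classes unless
    ``confidence_by_class`` maps each class to its own family.
    class_bias: probability of calling deleterious on an unlabeled
    mutation when the draw comes out wrong — for labeled binary data a
    wrong call is necessarily the opposite class, so it only matters for
    unlabeled input.
    For categorical tools the drawn confidence is discretised into
    low/medium/high tokens by equal thirds of its support.
    """

    name: str
    score_kind: str = CONTINUOUS
    accuracy_curve: tuple = ("identity",)
    confidence: tuple = ("uniform", 0.5, 1.0)
    confidence_by_class: dict[str, tuple] | None = None
    missing_rate: float = 0.0
    class_bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.class_bias <= 1.0:
            raise ValidationError("class_bias must be in [0, 1]")
        if self.score_kind not in (CONTINUOUS, CATEGORICAL):
            raise ValidationError(f"bad score_kind {self.score_kind!r}")

    def accuracy_at(self, c: np.ndarray) -> np.ndarray:
        kind = self.accuracy_curve[0]
        if kind == "constant":
            return np.full_like(c, float(self.accuracy_curve[1]))
        if kind == "identity":
            return np.clip(c, 0.0, 1.0)
        if kind == "logistic":
            slope, mid = self.accuracy_curve[1], self.accuracy_curve[2]
            return 1.0 / (1.0 + np.exp(-slope * (c - mid)))
        raise ValidationError(f"unknown accuracy curve {kind!r}")

    def _dist_for(self, label: str) -> tuple:
        if self.confidence_by_class is not None:
            return self.confidence_by_class[label]
        return self.confidence

    def draw_confidence(
        self, labels: Sequence[str], rng: np.random.Generator
    ) -> np.ndarray:
        out = np.empty(len(labels))
        for cls in (NEUTRAL, DELETERIOUS):
            idx = np.array([lab == cls for lab in labels])
            if not idx.any():
                continue
            dist = self._dist_for(cls)
            if dist[0] == "uniform":
                draws = rng.uniform(dist[1], dist[2], size=int(idx.sum()))
            elif dist[0] == "beta":
                draws = rng.beta(dist[1], dist[2], size=int(idx.sum()))
            else:
                raise ValidationError(f"unknown confidence family {dist[0]!r}")
            out[idx] = draws
        return out

    def support(self) -> tuple[float, float]:
        dists = (
            list(self.confidence_by_class.values())
            if self.confidence_by_class
            else [self.confidence]
        )
        lo = min(d[1] if d[0] == "uniform" else 0.0 for d in dists)
        hi = max(d[2] if d[0] == "uniform" else 1.0 for d in dists)
        return lo, hi


def default_profiles() -> tuple[ToolProfile, ...]:
    """Six-tool ensemble spanning the accuracy range of real predictors.

    Marginal accuracies fall in 0.65-0.75.  Five tools have informative
    confidences (accuracy rises with confidence); one reports an
    uninformative confidence at constant accuracy, and two are
    categorical.  Missingness spans 0 to 0.4, with at least one
    full-coverage tool so the consensus always has a vote.
    """
    return (
        ToolProfile(
            "sim_evo", CONTINUOUS, ("identity",), ("uniform", 0.55, 0.95),
            missing_rate=0.0,
        ),
        ToolProfile(
            "sim_phys", CONTINUOUS, ("identity",), ("uniform", 0.50, 0.90),
            missing_rate=0.10,
        ),
        ToolProfile(
            "sim_ml", CONTINUOUS, ("logistic", 6.0, 0.55),
            ("uniform", 0.40, 1.00), missing_rate=0.20,
        ),
        ToolProfile(
            "sim_rules", CATEGORICAL, ("identity",), ("uniform", 0.55, 0.85),
            missing_rate=0.30,
        ),
        ToolProfile(
            "sim_flat", CONTINUOUS, ("constant", 0.70), ("uniform", 0.0, 1.0),
            missing_rate=0.40,
        ),
        ToolProfile(
            "sim_hmm", CATEGORICAL, ("identity",), ("uniform", 0.60, 0.90),
            missing_rate=0.05,
        ),
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Full description of one simulated benchmark + predictor ensemble."""

    profiles: tuple[ToolProfile, ...] = field(default_factory=default_profiles)
    rho: float = 0.2
    n: int = 20_000
    class_balance: float = 0.5  # neutral fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must be in [0, 1)")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if not 0.0 < self.class_balance < 1.0:
            raise ValidationError("class_balance must be in (0, 1)")


def _sub_rng(seed: int, *streams: str) -> np.random.Generator:
    """Independent generator for a named stream, stable across tool sets."""
    keys = [seed] + [zlib.crc32(s.encode()) for s in streams]
    return np.random.default_rng(keys)


def generate_mutations(
    n: int,
    class_balance: float = 0.5,
    seed: int = 0,
    aa_freqs: dict[str, float] | None = None,
    proteins: int = 50,
    protein_length: int = 400,
) -> list[MutationRecord]:
    """Draw n labeled synthetic substitutions.

    ``class_balance`` is the neutral fraction; residues are drawn from
    ``aa_freqs`` (background database frequencies by default), resampling
    the mutant residue until it differs from the wild type.  Deterministic
    given the seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0.0 < class_balance < 1.0:
        raise ValidationError("class_balance must be in (0, 1)")
    freqs = aa_freqs or BACKGROUND_AA_FREQS
    aas = list(AMINO_ACIDS)
    p = np.array([freqs[a] for a in aas])
    p = p / p.sum()
    rng = _sub_rng(seed, "mutations")
    pids = rng.integers(0, proteins, size=n)
    positions = rng.integers(1, protein_length + 1, size=n)
    labels = np.where(
        rng.random(n) < class_balance, NEUTRAL, DELETERIOUS
    )
    wt = rng.choice(aas, size=n, p=p)
    mut = rng.choice(aas, size=n, p=p)
    clash = mut == wt
    while clash.any():
        mut[clash] = rng.choice(aas, size=int(clash.sum()), p=p)
        clash = mut == wt
    records = []
    seen: set = set()
    for i in range(n):
        pid = f"SYN{pids[i]:04d}"
        key = (pid, int(positions[i]), wt[i], mut[i])
        if key in seen:  # keep keys unique: bump the position
            pos = int(positions[i])
            while (pid, pos, wt[i], mut[i]) in seen:
                pos += 1
            key = (pid, pos, wt[i], mut[i])
        seen.add(key)
        records.append(
            MutationRecord(
                protein_id=key[0],
                position=key[1],
                wt_aa=key[2],
                mut_aa=key[3],
                label=str(labels[i]),
                source="simulated",
            )
        )
    return records


_TOKENS = ("low", "medium", "high")


def simulate_tool(
    profile: ToolProfile,
    mutations: Sequence[MutationRecord],
    latent: np.ndarray,
    rho: float,
    seed: int,
) -> list[ToolPrediction]:
    """Simulate one tool's predictions over a mutation set.

    ``latent`` is the shared per-mutation uniform difficulty draw; with
    probability ``rho`` the tool thresholds it instead of a private draw,
    which couples tools without changing any marginal accuracy.
    """
    n = len(mutations)
    rng = _sub_rng(seed, "tool", profile.name)
    labels = [m.label for m in mutations]
    conf = profile.draw_confidence(labels, rng)
    acc = profile.accuracy_at(conf)
    use_shared = rng.random(n) < rho
    private = rng.random(n)
    threshold_draw = np.where(use_shared, latent, private)
    correct = threshold_draw < acc
    missing = rng.random(n) < profile.missing_rate

    lo, hi = profile.support()
    span = (hi - lo) or 1.0
    predictions = []
    for i, m in enumerate(mutations):
        if missing[i]:
            predictions.append(
                ToolPrediction(
                    *m.key,
                    tool=profile.name,
                    predicted_class=MISSING,
                    raw_confidence=None,
                    score_kind=profile.score_kind,
                )
            )
            continue
        truth = m.label
        if truth in (NEUTRAL, DELETERIOUS):
            if correct[i]:
                cls = truth
            else:
                cls = DELETERIOUS if truth == NEUTRAL else NEUTRAL
        else:  # unlabeled input: class_bias decides the call direction
            cls = (
                DELETERIOUS
                if rng.random() < profile.class_bias
                else NEUTRAL
            )
        if profile.score_kind == CONTINUOUS:
            raw: float | str = float(conf[i])
        else:
            tercile = min(2, int((conf[i] - lo) / span * 3))
            raw = _TOKENS[tercile]
        predictions.append(
            ToolPrediction(
                *m.key,
                tool=profile.name,
                predicted_class=cls,
                raw_confidence=raw,
                score_kind=profile.score_kind,
            )
        )
    return predictions


def simulate_ensemble(
    spec: EnsembleSpec,
) -> tuple[list[MutationRecord], list[ToolPrediction]]:
    """Generate a benchmark and all tool predictions under one spec.

    One shared latent difficulty per mutation couples the tools (weight
    ``spec.rho``); each tool consumes an independent sub-seeded stream, so
    adding or removing a tool never perturbs the others.
    """
    mutations = generate_mutations(
        spec.n, spec.class_balance, seed=spec.seed
    )
    latent = _sub_rng(spec.seed, "latent").random(spec.n)
    predictions: list[ToolPrediction] = []
    for profile in spec.profiles:
        predictions.extend(
            simulate_tool(profile, mutations, latent, spec.rho, spec.seed)
        )
    return mutations, predictions
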