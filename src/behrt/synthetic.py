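"""Seeded simulator of longitudinal coded-EHR corpora with planted structure.

The generator stands in for a large primary-care cohort that cannot be
shipped.  It plants exactly the statistical regularities the downstream
model is supposed to exploit, so that every stage of the pipeline can be
tested against known ground truth:

* diseases are partitioned into groups; each visit has a latent "active
  group" that evolves as a first-order Markov chain with a self-transition
  bias, so consecutive visits share context (trajectory signal for MLM
  and for next-visit prediction);
* codes inside a visit are drawn mostly from the active group
  (``within_group_affinity``-weighted), creating within-group
  co-occurrence;
* the initial active group depends on the patient's starting age (each
  group has a preferred age window), so age carries predictive signal;
* a latent binary attribute (a gender-analog) forbids a fraction of
  codes for one attribute level — the hook for the consistency audit;
* inter-visit gaps are irregular (truncated-normal months) and follow-up
  extends a fixed number of months past the last visit, which gates the
  6/12-month horizon tasks.

Identical seeds produce byte-identical JSONL corpora.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .corpus import PatientRecord, Visit

_GROUP_AGE_SPAN = (20.0, 80.0)  # preferred-age centers are spread over this range
_GROUP_AGE_WIDTH = 15.0         # sd (years) of each group's age preference


@dataclass
class SimConfig:
    """Study conditions for one synthetic corpus.

    Defaults define the desk-scale reference corpus: 2,000 patients and
    60 codes in 6 groups of 10, one fifth of the codes restricted to a
    single attribute level.
    """

    n_patients: int = 2000
    n_codes: int = 60
    n_groups: int = 6
    codes_per_group: int = 10
    attribute_exclusive_fraction: float = 0.2
    within_group_affinity: float = 25.0
    age_start_distribution: tuple[float, float] = (40.0, 15.0)  # years (mean, sd)
    visit_gap_distribution: tuple[float, float] = (6.0, 4.0)    # months (mean, sd)
    visits_range: tuple[int, int] = (5, 16)
    codes_per_visit_range: tuple[int, int] = (1, 4)
    follow_up_months: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_groups * self.codes_per_group > self.n_codes:
            raise ValueError("n_groups * codes_per_group must not exceed n_codes")
        if not (0.0 <= self.attribute_exclusive_fraction <= 1.0):
            raise ValueError("attribute_exclusive_fraction must lie in [0, 1]")
        if self.visits_range[0] < 5:
            raise ValueError("minimum visit count must be at least 5")
        if self.visits_range[0] > self.visits_range[1]:
            raise ValueError("visits_range must be (min, max) with min <= max")
        if self.codes_per_visit_range[0] < 1:
            raise ValueError("visits must carry at least one code")
        if self.within_group_affinity <= 0:
            raise ValueError("within_group_affinity must be positive")


@dataclass
class GroundTruth:
    """Planted structure: code -> group, and code -> allowed attribute.

    ``allowed_attribute[code]`` is 0 or 1 for attribute-exclusive codes
    and ``None`` for codes both attribute levels may carry.
    """

    group_of_code: dict[str, int]
    allowed_attribute: dict[str, Optional[int]]

    def exclusive_codes(self) -> list[str]:
        return [c for c, a in self.allowed_attribute.items() if a is not None]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"group_of_code": self.group_of_code,
                 "allowed_attribute": self.allowed_attribute},
                fh, indent=1,
            )

    @classmethod
    def load(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            group_of_code={c: int(g) for c, g in obj["group_of_code"].items()},
            allowed_attribute={
                c: (None if a is None else int(a))
                for c, a in obj["allowed_attribute"].items()
            },
        )


def _code_name(i: int) -> str:
    return f"D{i:03d}"


def generate_corpus(config: SimConfig) -> tuple[list[PatientRecord], GroundTruth]:
    """Draw a corpus from the planted generative model (fully seeded)."""
    rng = np.random.default_rng(config.seed)
    n_codes, n_groups = config.n_codes, config.n_groups
    codes = [_code_name(i) for i in range(n_codes)]

    # Group assignment: blocks of codes_per_group; leftovers round-robin.
    group_of = np.empty(n_codes, dtype=np.int64)
    block = n_groups * config.codes_per_group
    group_of[:block] = np.arange(block) // config.codes_per_group
    if block < n_codes:
        group_of[block:] = np.arange(n_codes - block) % n_groups

    # Attribute-exclusive codes, alternating allowed level for balance.
    n_excl = int(round(config.attribute_exclusive_fraction * n_codes))
    excl_idx = np.sort(rng.choice(n_codes, size=n_excl, replace=False))
    allowed = np.full(n_codes, -1, dtype=np.int64)  # -1 = both levels
    allowed[excl_idx] = np.arange(n_excl) % 2

    centers = np.linspace(*_GROUP_AGE_SPAN, n_groups) if n_groups > 1 else np.array(
        [np.mean(_GROUP_AGE_SPAN)]
    )
    affinity = config.within_group_affinity
    stay = affinity / (affinity + (n_groups - 1)) if n_groups > 1 else 1.0

    gap_mean, gap_sd = config.visit_gap_distribution
    age_mean, age_sd = config.age_start_distribution
    cmin, cmax = config.codes_per_visit_range
    vmin, vmax = config.visits_range

    corpus: list[PatientRecord] = []
    for p in range(config.n_patients):
        attr = int(rng.integers(2))
        ok = allowed != 1 - attr  # codes this patient may carry
        if ok.sum() < cmin:
            raise ValueError("infeasible config: too few codes allowed per attribute")
        month = max(0, int(round(12 * rng.normal(age_mean, age_sd))))
        n_visits = int(rng.integers(vmin, vmax + 1))

        # Age-dependent initial group.
        w0 = np.exp(-0.5 * ((month / 12.0 - centers) / _GROUP_AGE_WIDTH) ** 2) + 1e-3
        group = int(rng.choice(n_groups, p=w0 / w0.sum()))

        visits = []
        last_visit_month = month
        for _ in range(n_visits):
            k = int(rng.integers(cmin, cmax + 1))
            w = np.where(group_of == group, affinity, 1.0) * ok
            k = min(k, int(ok.sum()))
            picked = rng.choice(n_codes, size=k, replace=False, p=w / w.sum())
            visits.append(Visit(age_years=month // 12, age_months=month,
                                codes=tuple(codes[i] for i in sorted(picked))))
            last_visit_month = month
            month += max(1, int(round(rng.normal(gap_mean, gap_sd))))
            if n_groups > 1 and rng.random() >= stay:
                # switches drift toward age-appropriate groups: disease
                # risk tracks the patient's current age
                wg = np.exp(-0.5 * ((month / 12.0 - centers)
                                    / _GROUP_AGE_WIDTH) ** 2) + 1e-3
                wg[group] = 0.0
                group = int(rng.choice(n_groups, p=wg / wg.sum()))

        obs_end = last_visit_month + config.follow_up_months
        corpus.append(
            PatientRecord(
                patient_id=f"P{p:05d}",
                visits=tuple(visits),
                observation_end_age_months=obs_end,
                attributes={"attribute": attr},
            )
        )

    truth = GroundTruth(
        group_of_code={codes[i]: int(group_of[i]) for i in range(n_codes)},
        allowed_attribute={
            codes[i]: (None if allowed[i] < 0 else int(allowed[i]))
            for i in range(n_codes)
        },
    )
    return corpus, truth


@dataclass
class CorpusSummary:
    """Population statistics of one corpus."""

    n_patients: int
    visits_per_patient: np.ndarray
    codes_per_visit: np.ndarray
    prevalence: pd.Series  # fraction of patients carrying each code

    def as_frame(self) -> pd.DataFrame:
        return self.prevalence.rename("prevalence").to_frame()


def summarize_corpus(corpus: list[PatientRecord]) -> CorpusSummary:
    """Patient/visit/code counts and per-code prevalence."""
    if not corpus:
        raise ValueError("cannot summarise an empty corpus")
    visits_pp = np.array([rec.n_visits for rec in corpus])
    codes_pv = np.array([len(v.codes) for rec in corpus for v in rec.visits])
    carriers: dict[str, int] = {}
    for rec in corpus:
        for code in {c for v in rec.visits for c in v.codes}:
            carriers[code] = carriers.get(code, 0) + 1
    prevalence = pd.Series(carriers, dtype=float).sort_index() / len(corpus)
    return CorpusSummary(
        n_patients=len(corpus),
        visits_per_patient=visits_pp,
        codes_per_visit=codes_pv,
        prevalence=prevalence,
    )
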