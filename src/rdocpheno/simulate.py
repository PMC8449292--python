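"""Synthetic lexicons, notes, and cohorts with known planted truth.

The generator emulates the statistical structure of a three-group psychiatric
admission cohort (depression / schizophrenia / bipolar disorder) so the whole
pipeline — text preparation, scoring, group comparison, regression — can be
tested end to end with no real data:

* **Lexicon**: synthetic token atoms, unique across terms and disjoint from
  the filler vocabulary, so a term can appear in a note only because it was
  planted (a configurable fraction of terms are two-word phrases, which stay
  contiguous because notes are assembled and shuffled at the unit level).
* **Notes**: for an admission in group *g*, each term of domain *d* is
  included independently with probability ``term_probs[g][d]``.  That makes
  the expected presence-fraction score exactly ``term_probs[g][d]`` — the
  ground truth is analytic, not simulated.
* **Cohort**: demographics per group (age, sex, Charlson index), a binary
  long-stay outcome drawn from a logistic model on the *realized* scores (in
  percentage points) and covariates, and a length of stay drawn from an
  arm-specific truncated log-normal so the 3-day dichotomization reproduces
  the drawn outcome exactly.  The binary outcome carries the planted
  regression signal; the duration is scenery around it.

Default sizes mirror the motivating study: 612/83/37 admissions over
465/73/33 patients (732 admissions, 571 patients).  Default per-domain term
probabilities are set to the observed group score means, and the default
outcome model plants a positive negative-valence effect and a negative
arousal effect, per percentage point.

Determinism: one global seed; each stage and each admission derives its own
substream (``SeedSequence(seed, spawn_key=(stage, index))``), so the cohort
generator and the note generator realize the *same* per-term inclusion draws
and pipeline scores equal the cohort's stored scores token for token.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from .cohort import DIAGNOSES, CohortTable, los_binary
from .errors import ValidationError
from .lexicon import CANONICAL_DOMAINS, Lexicon
from .text import DictionaryProvider, NoteDocument

__all__ = [
    "LosModel",
    "GeneratorSpec",
    "PlantedTruth",
    "generate_lexicon",
    "generate_cohort",
    "generate_notes",
    "make_stub_dictionary",
    "write_truth",
]

# substream stage keys
_S_LEXICON, _S_DEMOG, _S_TERMS, _S_NOTES, _S_OUTCOME, _S_ASSIGN = range(6)

_MAX_TERMS = 100_000


@dataclass(frozen=True)
class LosModel:
    """Logistic model for the >3-day outcome plus the per-arm duration model.

    ``domain_coefs`` are log-odds per score percentage point.  Durations are
    log-normal within outcome arm, truncated to respect the 3-day split
    (long: > threshold; short: (0, threshold]).
    """

    intercept: float = 0.75
    domain_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "negative_valence": math.log(1.06),
            "arousal_regulatory": math.log(0.95),
        }
    )
    age_coef: float = 0.0
    cci_coef: float = 0.0
    female_coef: float = 0.0
    threshold: float = 3.0
    # (mu, sigma) of log(days)
    long_lognorm: tuple[float, float] = (math.log(9.0), 0.7)
    short_lognorm: tuple[float, float] = (math.log(1.5), 0.45)


def _default_term_probs() -> dict[str, dict[str, float]]:
    # Group-level expected domain scores (fraction scale).
    return {
        "depression": {
            "positive_valence": 0.112,
            "negative_valence": 0.146,
            "cognitive_systems": 0.156,
            "social_processes": 0.112,
            "arousal_regulatory": 0.101,
        },
        "schizophrenia": {
            "positive_valence": 0.108,
            "negative_valence": 0.099,
            "cognitive_systems": 0.189,
            "social_processes": 0.168,
            "arousal_regulatory": 0.080,
        },
        "bipolar_disorder": {
            "positive_valence": 0.098,
            "negative_valence": 0.100,
            "cognitive_systems": 0.189,
            "social_processes": 0.176,
            "arousal_regulatory": 0.102,
        },
    }


def _default_demographics() -> dict[str, dict[str, float]]:
    # age mean/SD, female fraction, mean Charlson index per group
    return {
        "depression": {"age_mean": 36.4, "age_sd": 18.3, "female_frac": 0.63, "cci_mean": 0.3},
        "schizophrenia": {"age_mean": 31.3, "age_sd": 15.3, "female_frac": 0.534, "cci_mean": 0.1},
        "bipolar_disorder": {"age_mean": 34.8, "age_sd": 14.7, "female_frac": 0.667, "cci_mean": 0.1},
    }


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything that determines a synthetic study: sizes, probabilities, models, seed."""

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"depression": 612, "schizophrenia": 83, "bipolar_disorder": 37}
    )
    patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"depression": 465, "schizophrenia": 73, "bipolar_disorder": 33}
    )
    term_probs: dict[str, dict[str, float]] = field(default_factory=_default_term_probs)
    n_domains: int = 5
    terms_per_domain: int = 40
    two_word_fraction: float = 0.25
    filler_vocab_size: int = 500
    note_filler_mean: float = 120.0
    demographics: dict[str, dict[str, float]] = field(default_factory=_default_demographics)
    los_model: LosModel = field(default_factory=LosModel)
    bilingual_fraction: float = 0.0

    def domain_names(self) -> tuple[str, ...]:
        if self.n_domains <= len(CANONICAL_DOMAINS):
            return CANONICAL_DOMAINS[: self.n_domains]
        extra = tuple(f"domain_{i:02d}" for i in range(len(CANONICAL_DOMAINS), self.n_domains))
        return CANONICAL_DOMAINS + extra

    def groups(self) -> tuple[str, ...]:
        return tuple(g for g in DIAGNOSES if g in self.group_sizes) + tuple(
            g for g in self.group_sizes if g not in DIAGNOSES
        )

    def validate(self) -> None:
        if self.n_domains < 1 or self.terms_per_domain < 1:
            raise ValidationError("need at least one domain and one term per domain")
        if self.n_domains * self.terms_per_domain > _MAX_TERMS:
            raise ValidationError(f"lexicon too large (> {_MAX_TERMS} unique terms)")
        if not 0 <= self.two_word_fraction <= 1 or not 0 <= self.bilingual_fraction <= 1:
            raise ValidationError("fractions must be in [0, 1]")
        for g in self.groups():
            if self.group_sizes[g] < 1:
                raise ValidationError(f"group {g}: need >= 1 admission")
            if g not in self.patients_per_group:
                raise ValidationError(f"group {g}: missing patient count")
            if not 1 <= self.patients_per_group[g] <= self.group_sizes[g]:
                raise ValidationError(f"group {g}: patients must be in [1, admissions]")
            for d in self.domain_names():
                p = self.term_probs.get(g, {}).get(d)
                if p is None or not 0 <= p <= 1:
                    raise ValidationError(f"term_probs[{g}][{d}] missing or outside [0, 1]")
        lm = self.los_model
        if norm.cdf((math.log(lm.threshold) - lm.short_lognorm[0]) / lm.short_lognorm[1]) < 1e-9:
            raise ValidationError("short-stay duration model has ~no mass below the threshold")
        if norm.sf((math.log(lm.threshold) - lm.long_lognorm[0]) / lm.long_lognorm[1]) < 1e-9:
            raise ValidationError("long-stay duration model has ~no mass above the threshold")


@dataclass(frozen=True)
class PlantedTruth:
    """The realized generating parameters a recovery test compares against."""

    spec: GeneratorSpec
    expected_scores: dict[str, dict[str, float]]  # group -> domain -> E[score] (= term prob)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self.spec)
        d["los_model"] = dataclasses.asdict(self.spec.los_model)
        return {"spec": d, "expected_scores": self.expected_scores}


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage, index)))


def generate_lexicon(spec: GeneratorSpec) -> Lexicon:
    """Deterministic synthetic lexicon: unique token atoms, disjoint domains."""
    spec.validate()
    rng = _rng(spec.seed, _S_LEXICON)
    terms: dict[str, frozenset[str]] = {}
    for di, d in enumerate(spec.domain_names()):
        ts = []
        for j in range(spec.terms_per_domain):
            if rng.random() < spec.two_word_fraction:
                ts.append(f"d{di}t{j}a d{di}t{j}b")
            else:
                ts.append(f"d{di}t{j}a")
        terms[d] = frozenset(ts)
    return Lexicon(domains=spec.domain_names(), terms=terms)


def _term_masks(spec: GeneratorSpec, admission_index: int, group: str) -> dict[str, np.ndarray]:
    """Per-term inclusion draws for one admission — shared by cohort and notes."""
    rng = _rng(spec.seed, _S_TERMS, admission_index)
    return {
        d: rng.random(spec.terms_per_domain) < spec.term_probs[group][d]
        for d in spec.domain_names()
    }


def _truncated_lognormal(u: np.ndarray, mu: float, sigma: float, lo: float | None, hi: float | None) -> np.ndarray:
    """Inverse-CDF sample of a log-normal truncated to (lo, hi]."""
    p_lo = norm.cdf((math.log(lo) - mu) / sigma) if lo else 0.0
    p_hi = norm.cdf((math.log(hi) - mu) / sigma) if hi else 1.0
    p = p_lo + u * (p_hi - p_lo)
    return np.exp(mu + sigma * ndtri(p))


def generate_cohort(spec: GeneratorSpec) -> tuple[CohortTable, PlantedTruth]:
    """Generate the admission table: demographics, realized scores, outcome, LOS.

    The realized domain scores are the exact presence fractions the notes of
    :func:`generate_notes` will produce, because both derive the per-term
    inclusion masks from the same per-admission substream.
    """
    spec.validate()
    domains = spec.domain_names()
    rows: list[dict] = []
    admission_index = 0
    patient_counter = 0

    for gi, g in enumerate(spec.groups()):
        n_adm, n_pat = spec.group_sizes[g], spec.patients_per_group[g]
        demo_rng = _rng(spec.seed, _S_DEMOG, gi)
        assign_rng = _rng(spec.seed, _S_ASSIGN, gi)
        dg = spec.demographics[g]

        ages = np.clip(np.rint(demo_rng.normal(dg["age_mean"], dg["age_sd"], n_pat)), 18, 90).astype(int)
        female = demo_rng.random(n_pat) < dg["female_frac"]
        # admission -> patient: everyone once, extras reassigned at random
        owners = list(range(n_pat)) + list(assign_rng.integers(0, n_pat, n_adm - n_pat))
        for owner in owners:
            pid = f"P{patient_counter + owner:05d}"
            aid = f"A{admission_index:06d}"
            masks = _term_masks(spec, admission_index, g)
            scores = {d: float(masks[d].mean()) for d in domains}
            cci = int(demo_rng.poisson(dg["cci_mean"]))
            rows.append(
                {
                    "patient_id": pid,
                    "admission_id": aid,
                    "diagnosis": g,
                    "age": int(ages[owner]),
                    "sex": "female" if female[owner] else "male",
                    "cci": cci,
                    "htn": int(demo_rng.random() < 0.12),
                    "dm": int(demo_rng.random() < 0.045),
                    "stroke": int(demo_rng.random() < 0.012),
                    "renal": int(demo_rng.random() < 0.02),
                    "pneumonia": int(demo_rng.random() < 0.04),
                    **scores,
                }
            )
            admission_index += 1
        patient_counter += n_pat

    df = pd.DataFrame(rows)

    lm = spec.los_model
    logit = np.full(len(df), lm.intercept)
    for d in domains:
        logit += lm.domain_coefs.get(d, 0.0) * df[d].to_numpy() * 100.0
    logit += lm.age_coef * df["age"].to_numpy()
    logit += lm.cci_coef * df["cci"].to_numpy()
    logit += lm.female_coef * (df["sex"] == "female").to_numpy()

    out_rng = _rng(spec.seed, _S_OUTCOME)
    y = out_rng.random(len(df)) < expit(logit)
    u = out_rng.random(len(df))
    los = np.where(
        y,
        _truncated_lognormal(u, *lm.long_lognorm, lo=lm.threshold, hi=None),
        _truncated_lognormal(u, *lm.short_lognorm, lo=None, hi=lm.threshold),
    )
    # guard against the truncation boundary itself under floating rounding
    los = np.where(y, np.maximum(los, np.nextafter(lm.threshold, np.inf)), np.minimum(los, lm.threshold))
    df["los_days"] = los
    assert (los_binary(df["los_days"].to_numpy(), lm.threshold) == y.astype(int)).all()

    df = df[
        ["patient_id", "admission_id", "diagnosis", "age", "sex", "los_days", "cci",
         "htn", "dm", "stroke", "renal", "pneumonia", *domains]
    ]
    truth = PlantedTruth(spec=spec, expected_scores={g: dict(spec.term_probs[g]) for g in spec.groups()})
    return CohortTable(df=df, unit="admission"), truth


def generate_notes(spec: GeneratorSpec, lexicon: Lexicon, cohort: CohortTable) -> list[NoteDocument]:
    """Assemble one note per admission, planting exactly the cohort's realized terms.

    Included terms and filler words are shuffled as units, so multi-word
    terms remain contiguous and the pipeline score equals the stored score.
    With ``bilingual_fraction`` > 0, that fraction of tokens is replaced by a
    synthetic foreign form that :func:`make_stub_dictionary` inverts.
    """
    if lexicon.domains != spec.domain_names():
        raise ValidationError("lexicon domains do not match the generator spec")
    sorted_terms = {d: sorted(lexicon.terms[d]) for d in lexicon.domains}
    for d in lexicon.domains:
        if len(sorted_terms[d]) != spec.terms_per_domain:
            raise ValidationError("lexicon size does not match the generator spec")
    filler = [f"filler{i}" for i in range(spec.filler_vocab_size)]

    docs: list[NoteDocument] = []
    for aid, g in zip(cohort.df["admission_id"], cohort.df["diagnosis"]):
        i = int(aid[1:])
        masks = _term_masks(spec, i, g)
        note_rng = _rng(spec.seed, _S_NOTES, i)
        units: list[tuple[str, ...]] = []
        for d in lexicon.domains:
            # sorted(lexicon.terms[d]) is deterministic; mask index j <-> j-th sorted term
            units.extend(tuple(t.split(" ")) for t, inc in zip(sorted_terms[d], masks[d]) if inc)
        n_fill = int(note_rng.poisson(spec.note_filler_mean))
        units.extend((w,) for w in note_rng.choice(filler, size=n_fill))
        order = note_rng.permutation(len(units))
        tokens = [tok for k in order for tok in units[k]]
        if spec.bilingual_fraction > 0:
            foreign = note_rng.random(len(tokens)) < spec.bilingual_fraction
            tokens = [f"zz{t}" if f else t for t, f in zip(tokens, foreign)]
        docs.append(NoteDocument(note_id=aid, admission_id=aid, raw_text=" ".join(tokens)))
    return docs


def make_stub_dictionary(spec: GeneratorSpec, lexicon: Lexicon) -> DictionaryProvider:
    """Provider inverting the simulator's synthetic foreign forms (``zzword`` -> ``word``)."""
    vocab = {tok for d in lexicon.domains for t in lexicon.terms[d] for tok in t.split(" ")}
    vocab.update(f"filler{i}" for i in range(spec.filler_vocab_size))
    return DictionaryProvider({f"zz{w}": w for w in vocab})


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.as_dict(), fh, indent=2)
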