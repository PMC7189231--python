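"""Data model and tokenisation for coded longitudinal EHR.

A patient's record is an ordered list of visits; each visit carries an
integer patient age (years) and a non-empty list of diagnosis codes.
Records are serialised one JSON object per line (JSONL).  Tokenisation
turns a record into the four parallel id channels the encoder consumes:

    [CLS] d d [SEP] d [SEP] d d d [SEP] [PAD] ...
    token  : disease / special ids
    age    : one id per integer year of age, shared by a whole visit
    segment: 0/1, alternating between consecutive visits
    position: the visit ordinal (CLS = 0, first visit = 1, ...)

All tokens of a visit — including its trailing [SEP] — share the same
age/segment/position ids, which makes the encoder order-invariant to the
arrangement of diagnoses inside a visit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

PAD_TOKEN = "[PAD]"
UNK_TOKEN = "[UNK]"
CLS_TOKEN = "[CLS]"
SEP_TOKEN = "[SEP]"
MASK_TOKEN = "[MASK]"
#: Special tokens in id order; ids 0..4.
SPECIAL_TOKENS = (PAD_TOKEN, UNK_TOKEN, CLS_TOKEN, SEP_TOKEN, MASK_TOKEN)

PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(len(SPECIAL_TOKENS))

#: Ages above this many years fall into a single "unknown age" bucket.
MAX_AGE_YEARS = 110
AGE_UNK_ID = MAX_AGE_YEARS + 1
AGE_VOCAB_SIZE = MAX_AGE_YEARS + 2

#: Sentinel used in label arrays for positions that carry no label.
IGNORE_LABEL = -100


@dataclass(frozen=True)
class DiseaseVocabulary:
    """Bijection between disease codes (plus specials) and contiguous ids.

    Special tokens occupy ids ``0..4``; the G disease codes follow in
    lexicographic order at ids ``5..G+4``.
    """

    codes: tuple[str, ...]
    code_to_id: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_codes(cls, codes: Iterable[str]) -> "DiseaseVocabulary":
        codes = tuple(sorted(set(codes)))
        if any(c in SPECIAL_TOKENS for c in codes):
            raise ValueError("disease codes may not collide with special tokens")
        mapping = {tok: i for i, tok in enumerate(SPECIAL_TOKENS)}
        mapping.update({c: len(SPECIAL_TOKENS) + i for i, c in enumerate(codes)})
        return cls(codes=codes, code_to_id=mapping)

    @property
    def n_diseases(self) -> int:
        return len(self.codes)

    @property
    def size(self) -> int:
        """Total id count: G diseases + 5 specials."""
        return len(self.codes) + len(SPECIAL_TOKENS)

    @property
    def first_disease_id(self) -> int:
        return len(SPECIAL_TOKENS)

    def encode_code(self, code: str) -> int:
        """Id of ``code``; unknown codes map to [UNK]."""
        return self.code_to_id.get(code, UNK_ID)

    def id_to_code(self, idx: int) -> str:
        if idx < len(SPECIAL_TOKENS):
            return SPECIAL_TOKENS[idx]
        return self.codes[idx - len(SPECIAL_TOKENS)]

    def disease_index(self, code: str) -> int:
        """0-based index of a disease code among the G diseases."""
        idx = self.code_to_id[code]
        if idx < len(SPECIAL_TOKENS):
            raise KeyError(f"{code!r} is a special token, not a disease")
        return idx - len(SPECIAL_TOKENS)

    def save(self, path) -> None:
        """Write one disease code per line; specials are implicit."""
        with open(path, "w") as fh:
            for code in self.codes:
                fh.write(code + "\n")

    @classmethod
    def load(cls, path) -> "DiseaseVocabulary":
        with open(path) as fh:
            codes = [line.strip() for line in fh if line.strip()]
        return cls.from_codes(codes)


@dataclass(frozen=True)
class Visit:
    """One clinical encounter: a non-empty set of codes at an integer age.

    ``age_months`` optionally carries month-level timing for the
    fixed-horizon prediction tasks; when absent it defaults to
    ``12 * age_years`` (year-level granularity).
    """

    age_years: int
    codes: tuple[str, ...]
    age_months: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "codes", tuple(self.codes))
        if len(self.codes) == 0:
            raise ValueError("a visit must carry at least one diagnosis code")
        if self.age_years < 0:
            raise ValueError("visit age must be non-negative")
        if self.age_months is not None and self.age_months // 12 != self.age_years:
            raise ValueError("age_months and age_years disagree")

    @property
    def month_age(self) -> int:
        """Age in months (exact if stored, else 12 * age_years)."""
        return 12 * self.age_years if self.age_months is None else self.age_months


@dataclass(frozen=True)
class PatientRecord:
    """Time-ordered visits plus the end-of-follow-up horizon.

    ``observation_end_age_months`` marks the last age (in months) up to
    which the record is known, used to decide eligibility for the
    fixed-horizon prediction tasks.  ``attributes`` holds latent labels
    (e.g. a binary gender-analog in synthetic corpora) used only for
    audits, never as model input.
    """

    patient_id: str
    visits: tuple[Visit, ...]
    observation_end_age_months: int
    attributes: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "visits", tuple(self.visits))
        months = [v.month_age for v in self.visits]
        if any(a > b for a, b in zip(months, months[1:])):
            raise ValueError(
                f"patient {self.patient_id!r}: visit ages must be non-decreasing"
            )
        if self.visits and self.observation_end_age_months < months[-1]:
            raise ValueError(
                f"patient {self.patient_id!r}: observation end precedes last visit"
            )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class TokenizedSequence:
    """Parallel id channels for one patient, right-padded to a fixed length."""

    token_ids: np.ndarray
    age_ids: np.ndarray
    segment_ids: np.ndarray
    position_ids: np.ndarray
    padding_mask: np.ndarray  # True at real (non-pad) positions
    patient_id: str

    def __post_init__(self):
        n = len(self.token_ids)
        for arr in (self.age_ids, self.segment_ids, self.position_ids, self.padding_mask):
            if len(arr) != n:
                raise ValueError("channel arrays must have equal length")

    @property
    def n_real(self) -> int:
        return int(self.padding_mask.sum())


def build_vocab(corpus: list[PatientRecord]) -> DiseaseVocabulary:
    """Vocabulary of every code observed in ``corpus`` (sorted) + specials."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    codes = {c for rec in corpus for v in rec.visits for c in v.codes}
    return DiseaseVocabulary.from_codes(codes)


def filter_inclusion(
    corpus: list[PatientRecord], min_visits: int = 5
) -> list[PatientRecord]:
    """Keep patients with at least ``min_visits`` visits, order preserved.

    Diagnosis-free visits cannot occur in a :class:`PatientRecord` (they
    are dropped at parse time), so the visit count here is the count of
    diagnosis-carrying visits.
    """
    return [rec for rec in corpus if rec.n_visits >= min_visits]


def age_to_id(age_years: int) -> int:
    """Map an integer age to its embedding id (one id per year, capped)."""
    if 0 <= age_years <= MAX_AGE_YEARS:
        return age_years
    return AGE_UNK_ID


def encode_visits(
    visits: tuple[Visit, ...],
    vocab: DiseaseVocabulary,
    max_len: int = 256,
    patient_id: str = "",
) -> TokenizedSequence:
    """Tokenise an ordered visit list into the four-channel layout.

    If the full sequence exceeds ``max_len``, whole oldest visits are
    dropped (the [CLS] is kept and the retained visits are renumbered
    from 1) until it fits; a single visit that cannot fit raises.
    """
    if not visits:
        raise ValueError("cannot encode an empty visit list")
    lengths = [len(v.codes) + 1 for v in visits]  # codes + trailing SEP
    start = 0
    while 1 + sum(lengths[start:]) > max_len and start < len(visits) - 1:
        start += 1
    if 1 + sum(lengths[start:]) > max_len:
        raise ValueError(
            f"patient {patient_id!r}: a single visit of {lengths[start] - 1} codes "
            f"does not fit in max_len={max_len}"
        )
    kept = visits[start:]

    tokens = [CLS_ID]
    ages = [age_to_id(kept[0].age_years)]
    segments = [0]
    positions = [0]
    for j, visit in enumerate(kept, start=1):
        vis_age = age_to_id(visit.age_years)
        vis_seg = (j - 1) % 2
        for code in visit.codes:
            tokens.append(vocab.encode_code(code))
            ages.append(vis_age)
            segments.append(vis_seg)
            positions.append(j)
        tokens.append(SEP_ID)
        ages.append(vis_age)
        segments.append(vis_seg)
        positions.append(j)

    n_real = len(tokens)
    pad = max_len - n_real

    def _arr(xs, fill=0):
        return np.asarray(xs + [fill] * pad, dtype=np.int64)

    return TokenizedSequence(
        token_ids=_arr(tokens, PAD_ID),
        age_ids=_arr(ages),
        segment_ids=_arr(segments),
        position_ids=_arr(positions),
        padding_mask=np.asarray([True] * n_real + [False] * pad, dtype=bool),
        patient_id=patient_id,
    )


def encode_patient(
    record: PatientRecord, vocab: DiseaseVocabulary, max_len: int = 256
) -> TokenizedSequence:
    """Tokenise one patient record (see :func:`encode_visits`)."""
    return encode_visits(record.visits, vocab, max_len, patient_id=record.patient_id)


def collate(seqs: list[TokenizedSequence], trim: bool = True) -> dict[str, np.ndarray]:
    """Stack sequences into [B, L] batch arrays, optionally trimming the
    shared padding tail to the longest real length in the batch."""
    length = max(s.n_real for s in seqs) if trim else len(seqs[0].token_ids)
    out = {
        "token_ids": np.stack([s.token_ids[:length] for s in seqs]),
        "age_ids": np.stack([s.age_ids[:length] for s in seqs]),
        "segment_ids": np.stack([s.segment_ids[:length] for s in seqs]),
        "position_ids": np.stack([s.position_ids[:length] for s in seqs]),
        "padding_mask": np.stack([s.padding_mask[:length] for s in seqs]),
    }
    return out


# ---------------------------------------------------------------------------
# Corpus I/O (JSONL; one patient object per line)
# ---------------------------------------------------------------------------

def _record_to_obj(rec: PatientRecord) -> dict:
    visits = []
    for v in rec.visits:
        obj = {"age": int(v.age_years), "codes": list(v.codes)}
        if v.age_months is not None:
            obj["age_months"] = int(v.age_months)
        visits.append(obj)
    return {
        "patient_id": rec.patient_id,
        "observation_end_age_months": int(rec.observation_end_age_months),
        "attributes": dict(rec.attributes),
        "visits": visits,
    }


def _obj_to_record(obj: dict) -> PatientRecord:
    visits = tuple(
        Visit(age_years=int(v["age"]), codes=tuple(v["codes"]),
              age_months=(int(v["age_months"]) if "age_months" in v else None))
        for v in obj["visits"]
        if v["codes"]  # diagnosis-free visits are dropped at parse time
    )
    return PatientRecord(
        patient_id=str(obj["patient_id"]),
        visits=visits,
        observation_end_age_months=int(obj["observation_end_age_months"]),
        attributes=obj.get("attributes", {}),
    )


def write_corpus(corpus: list[PatientRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in corpus:
            fh.write(json.dumps(_record_to_obj(rec)) + "\n")


def read_corpus(path) -> list[PatientRecord]:
    """Read a JSONL corpus; malformed lines raise with their line number."""
    corpus: list[PatientRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                corpus.append(_obj_to_record(obj))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: invalid record on line {lineno}: {exc}") from exc
    return corpus
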