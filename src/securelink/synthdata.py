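"""Synthetic populations and producer files with ground-truth linkage.

Real administrative files cannot be shipped, so every test input is
generated: a population of persons with French-style identifiers — family
name, first name, sex, date of birth, and a NIR-like national number
(13 structured digits plus a 2-digit control key, ``97 - (number mod 97)``)
— split into two producer files with a configurable overlap, each copy
independently corrupted by the error processes linkage must tolerate
(typos, name changes, missing fields, day/month swaps).

Ground truth is person-level: the generator records which record of file A
and which record of file B belong to the same person, so linkage output can
be scored exactly. Errors are independent per field and per file copy;
correlated errors (household effects, systematic transcription habits) are
deliberately not modelled.

The :func:`evaluate` scorer follows the standard confusion terminology of
the field: a missed true pair is a *duplicate* (false negative — the person
ends up represented twice), a wrongly linked pair is a *collision* (false
positive — two people merged into one).
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FieldErrorRates", "ErrorConfig", "SynthError",
    "SURNAMES", "FORENAMES_M", "FORENAMES_F",
    "nir_checksum", "validate_nir", "generate_population",
    "make_producer_files", "evaluate",
]


class SynthError(ValueError):
    """Invalid generator configuration or input."""


# Bundled name pools; accented forms included on purpose, to exercise
# accent-stripping and phonetic normalization downstream.
SURNAMES = (
    "Dupont", "Dupond", "Durand", "Martin", "Bernard", "Petit", "Moreau",
    "Lefèvre", "Lefebvre", "Leroy", "Roux", "Fournier", "Girard", "Bonnet",
    "Mercier", "Blanchard", "Gauthier", "Noël", "Perrot", "Chevalier",
    "Benoît", "Renard", "Côté", "Lemaître", "Schmitt", "Muller", "Garnier",
    "Faure", "Rousseau", "Vincent", "Lambert", "Fontaine", "Chevallier",
    "Robin", "Masson", "Sanchez", "Gérard", "Nguyen", "Boyer", "Denis",
)
FORENAMES_M = (
    "Jean", "Pierre", "François", "Michel", "André", "René", "Louis",
    "Alain", "Jérôme", "Étienne", "Grégoire", "Théo", "Sébastien", "Hervé",
    "Benoît", "Rémi", "Clément", "Gaël", "Frédéric", "Nicolas",
)
FORENAMES_F = (
    "Marie", "Jeanne", "Françoise", "Éléonore", "Hélène", "Cécile", "Agnès",
    "Amélie", "Chloé", "Inès", "Léa", "Noémie", "Renée", "Zoé", "Margaux",
    "Aurélie", "Camille", "Sophie", "Valérie", "Anaïs",
)

_IDENTIFIER_FIELDS = ("family_name", "first_name", "birth_date", "nir")


def nir_checksum(number: int) -> int:
    """Control key of a 13-digit national number: ``97 - (number mod 97)``.

    The key lies in [1, 97]; a single corrupted digit changes the residue
    mod 97 with probability ~96/97, so the key detects almost all typos.
    """
    if not (0 <= number < 10 ** 13):
        raise SynthError(f"NIR body must be a 13-digit non-negative integer, got {number}")
    return 97 - (number % 97)


def validate_nir(nir: str) -> bool:
    """Check a 15-character NIR string (13-digit body + 2-digit key)."""
    if len(nir) != 15 or not nir.isdigit():
        return False
    return nir_checksum(int(nir[:13])) == int(nir[13:])


def generate_population(n: int, seed: int | None = None) -> pd.DataFrame:
    """Draw ``n`` synthetic persons, reproducibly per seed.

    Columns: ``person_id``, ``family_name``, ``first_name``, ``sex`` (1/2),
    ``birth_date`` (``dd/mm/yyyy``), ``nir`` (15-char string, checksum
    valid, unique, year/month digits consistent with the birth date), plus
    nothing else — payload attributes are added per producer file.
    """
    if n < 0:
        raise SynthError("n must be >= 0")
    if n > 5_000_000:
        raise SynthError("n exceeds the NIR order-number capacity of the generator")
    rng = random.Random(seed)
    rows = []
    seen_nirs: set[str] = set()
    for pid in range(n):
        sex = rng.choice((1, 2))
        year = rng.randint(1920, 2005)
        month = rng.randint(1, 12)
        day = rng.randint(1, 28)
        # department 01–95, Corsica (2A/2B) excluded to keep the body numeric
        dept = rng.randint(1, 95)
        while True:
            commune = rng.randint(1, 999)
            order = rng.randint(1, 999)
            body = int(f"{sex}{year % 100:02d}{month:02d}{dept:02d}"
                       f"{commune:03d}{order:03d}")
            nir = f"{body:013d}{nir_checksum(body):02d}"
            if nir not in seen_nirs:
                seen_nirs.add(nir)
                break
        forenames = FORENAMES_M if sex == 1 else FORENAMES_F
        rows.append({
            "person_id": pid,
            "family_name": rng.choice(SURNAMES),
            "first_name": rng.choice(forenames),
            "sex": sex,
            "birth_date": f"{day:02d}/{month:02d}/{year:04d}",
            "nir": nir,
        })
    return pd.DataFrame(rows, columns=["person_id", "family_name", "first_name",
                                       "sex", "birth_date", "nir"])


# --- error injection ---------------------------------------------------------

@dataclass(frozen=True)
class FieldErrorRates:
    """Independent per-copy probabilities of each typo process on one field."""

    substitution: float = 0.0
    transposition: float = 0.0
    deletion: float = 0.0
    insertion: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{f.name} rate must be in [0, 1], got {v}")


@dataclass(frozen=True)
class ErrorConfig:
    """Error processes applied to each producer file copy.

    ``overlap`` is the fraction of the population present in both files;
    all other rates are per record, per file copy, independent across
    fields. The defaults describe clean files (no errors, 60 % overlap).
    """

    field_errors: Mapping[str, FieldErrorRates] = field(default_factory=dict)
    name_change_rate: float = 0.0     # family name replaced outright (marriage etc.)
    missing_rate: float = 0.0         # identifier field blanked
    date_swap_rate: float = 0.0       # day and month exchanged when both <= 12
    overlap: float = 0.6

    def __post_init__(self) -> None:
        for name, v in (("name_change_rate", self.name_change_rate),
                        ("missing_rate", self.missing_rate),
                        ("date_swap_rate", self.date_swap_rate),
                        ("overlap", self.overlap)):
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0, 1], got {v}")
        for f in self.field_errors:
            if f not in _IDENTIFIER_FIELDS:
                raise SynthError(f"unknown identifier field {f!r} in field_errors")


def _typo(value: str, rates: FieldErrorRates, rng: random.Random, alphabet: str) -> str:
    if rates.substitution and rng.random() < rates.substitution and value:
        i = rng.randrange(len(value))
        repl = rng.choice([c for c in alphabet if c != value[i]])
        value = value[:i] + repl + value[i + 1:]
    if rates.transposition and rng.random() < rates.transposition and len(value) > 1:
        i = rng.randrange(len(value) - 1)
        value = value[:i] + value[i + 1] + value[i] + value[i + 2:]
    if rates.deletion and rng.random() < rates.deletion and value:
        i = rng.randrange(len(value))
        value = value[:i] + value[i + 1:]
    if rates.insertion and rng.random() < rates.insertion:
        i = rng.randrange(len(value) + 1)
        value = value[:i] + rng.choice(alphabet) + value[i:]
    return value


def _corrupt_record(row: dict, config: ErrorConfig, rng: random.Random) -> dict:
    out = dict(row)
    if config.name_change_rate and rng.random() < config.name_change_rate:
        out["family_name"] = rng.choice(
            [s for s in SURNAMES if s != out["family_name"]])
    if config.date_swap_rate and rng.random() < config.date_swap_rate:
        d, m, y = out["birth_date"].split("/")
        if int(d) <= 12 and d != m:
            out["birth_date"] = f"{m}/{d}/{y}"
    for fld, rates in config.field_errors.items():
        alphabet = string.digits if fld == "nir" else string.ascii_lowercase
        out[fld] = _typo(str(out[fld]), rates, rng, alphabet)
    if config.missing_rate:
        for fld in _IDENTIFIER_FIELDS:
            if rng.random() < config.missing_rate:
                out[fld] = ""
    return out


def make_producer_files(pop: pd.DataFrame, error_config: ErrorConfig | None = None,
                        seed: int | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a population into two producer files plus the ground truth.

    An ``overlap`` fraction of persons appears in both files; the rest is
    divided between the files. Each file copy is corrupted independently,
    then receives distinct payload columns — hospitalization attributes in
    file A, vital-status attributes in file B, after the classic use case
    of linking hospital data with mortality data. Returns
    ``(file_a, file_b, truth)`` where truth lists the true cross-file pairs
    as ``(seq_a, seq_b)``.
    """
    config = error_config or ErrorConfig()
    rng = random.Random(seed)
    persons = pop.to_dict("records")
    rng.shuffle(persons)
    n_overlap = round(config.overlap * len(persons))
    both, rest = persons[:n_overlap], persons[n_overlap:]
    only_a, only_b = rest[::2], rest[1::2]

    def build(members: list[dict], payload_maker) -> pd.DataFrame:
        rows = []
        for seq, person in enumerate(members, start=1):
            row = _corrupt_record(person, config, rng)
            row["seq"] = seq
            row.update(payload_maker())
            rows.append(row)
        cols = ["seq", "person_id", "family_name", "first_name", "sex",
                "birth_date", "nir"]
        frame = pd.DataFrame(rows)
        extras = [c for c in frame.columns if c not in cols]
        return frame[cols + extras]

    members_a = both + only_a
    members_b = both + only_b
    rng.shuffle(members_a)
    rng.shuffle(members_b)
    file_a = build(members_a, lambda: {"admission_year": rng.randint(2015, 2023),
                                       "length_of_stay": rng.randint(1, 30)})
    file_b = build(members_b, lambda: {"vital_status": rng.choice((0, 1)),
                                       "followup_year": rng.randint(2016, 2024)})

    truth = (file_a[["seq", "person_id"]].rename(columns={"seq": "seq_a"})
             .merge(file_b[["seq", "person_id"]].rename(columns={"seq": "seq_b"}),
                    on="person_id")[["seq_a", "seq_b"]]
             .sort_values(["seq_a", "seq_b"]).reset_index(drop=True))
    return file_a, file_b, truth


# --- scoring -----------------------------------------------------------------

def evaluate(decisions: pd.DataFrame, truth: pd.DataFrame,
             valid_ids_a: set | None = None,
             valid_ids_b: set | None = None) -> dict:
    """Confusion counts and precision/recall of a linkage run.

    ``decisions`` must carry ``id_a``, ``id_b`` and ``category`` columns
    (as produced by the linkage pipeline); ``truth`` carries ``seq_a``,
    ``seq_b``. The evaluated pair universe is the decision set: pairs that
    were never candidates (lost by blocking) count as false negatives.
    Indecision pairs are excluded from the matched/unmatched counts and
    reported separately, split by their true status.
    """
    if valid_ids_a is not None:
        bad = set(decisions["id_a"]) - valid_ids_a
        if bad:
            raise SynthError(f"decisions reference unknown id_a values: {sorted(bad)[:5]}")
    if valid_ids_b is not None:
        bad = set(decisions["id_b"]) - valid_ids_b
        if bad:
            raise SynthError(f"decisions reference unknown id_b values: {sorted(bad)[:5]}")

    true_pairs = set(zip(truth["seq_a"], truth["seq_b"]))
    matched = set(zip(decisions.loc[decisions["category"] == "matched", "id_a"],
                      decisions.loc[decisions["category"] == "matched", "id_b"]))
    indecision = set(zip(decisions.loc[decisions["category"] == "indecision", "id_a"],
                         decisions.loc[decisions["category"] == "indecision", "id_b"]))
    unmatched = set(zip(decisions.loc[decisions["category"] == "unmatched", "id_a"],
                        decisions.loc[decisions["category"] == "unmatched", "id_b"]))

    tp = len(matched & true_pairs)
    fp = len(matched - true_pairs)                      # collisions
    fn = len(true_pairs - matched - indecision)         # duplicates
    tn = len(unmatched - true_pairs)
    counts = {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "true_negatives": tn,
        "indecision_true": len(indecision & true_pairs),
        "indecision_false": len(indecision - true_pairs),
        "n_truth": len(true_pairs),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / len(true_pairs) if true_pairs else float("nan"),
    }
    return counts
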