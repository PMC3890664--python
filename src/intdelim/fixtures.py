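"""Packaged study data for the *Liolaemus walkeri* complex.

Two kinds of fixtures ship with the package:

* per-taxon summary statistics (mean, SD, n) of the morphometric and
  meristic characters of the five focal samples (Ancash, Ayacucho,
  Cusco, *L. tacnae*, *L. walkeri*), as CSV under ``intdelim/data``;
* the discrete binary character matrix, reconstructed at individual
  level from the published per-taxon/per-sex state summaries by
  :func:`walkeri_character_matrix`.

The published summary table reports n = 41 (*L. tacnae*) and n = 78
(*L. walkeri*) while the tolerance-interval tables use 42 and 79; the
source never reconciles the two.  The CSVs therefore carry an explicit
``n`` column holding the tolerance-stage n, and n is never re-derived.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .datatypes import CharacterMatrix, ContinuousSummary
from .io import read_continuous_summary

TAXA = ("Ancash", "Ayacucho", "Cusco", "tacnae", "walkeri")

#: sample sizes of the discrete matrix, per taxon: (n females, n males)
DISCRETE_N = {
    "Ancash": (18, 12),
    "Ayacucho": (18, 10),
    "Cusco": (8, 8),
    "tacnae": (23, 18),
    "walkeri": (48, 21),
}

#: characters only scorable on adult males (ventral pattern / pore characters)
ADULT_MALE_CHARACTERS = (
    "precloacal_pores",
    "melanistic_belly",
    "ringed_ventral_tail",
)

# Published per-taxon/sex states: "yes" (all 1), "no" (all 0) or a mixed
# cell. A mixed cell is written as the frequency of state 1 actually
# reported where one is (lateral-field marks in L. walkeri: 90% of
# individuals carry marks); otherwise as the uninformative 0.5.
_Y, _N, _M = 1.0, 0.0, 0.5
_TABLE1 = {
    #                    Ancash      Ayacucho    Cusco       tacnae      walkeri
    #                    (F,   M)    (F,   M)    (F,   M)    (F,   M)    (F,   M)
    "temporal_scales_smooth": ((_Y, _M), (_M, _M), (_Y, _Y), (_M, _Y), (_Y, _M)),
    "dorsal_head_smooth":     ((_M, _M), (_M, _M), (_Y, _M), (_M, _Y), (_M, _M)),
    "nasal_contacts_rostral": ((_M, _M), (_M, _Y), (_M, _M), (_M, _M), (_Y, _M)),
    "dorsal_scales_mucronate": ((_N, _N), (_M, _M), (_N, _N), (_N, _N), (_N, _N)),
    "precloacal_pores":       ((_N, _N), (_N, _Y), (_N, _Y), (_N, _N), (_N, _Y)),
    "subocular_color_differs": ((_M, _M), (_M, _M), (_M, _M), (_M, _M), (_M, _M)),
    "dorsal_head_marks":      ((_Y, _Y), (_M, _M), (_M, _Y), (_M, _M), (_M, _M)),
    "black_line_interparietal": ((_M, _M), (_M, _M), (_M, _M), (_M, _M), (_M, _M)),
    "paravertebral_marks":    ((_M, _N), (_Y, _M), (_M, _N), (_M, _M), (_M, _M)),
    "lateral_field_marks":    ((_Y, _Y), (_Y, _Y), (_N, _N), (_M, _M), (0.9, 0.9)),
    "dorsolateral_stripes":   ((_Y, _M), (_Y, _Y), (_Y, _Y), (_Y, _M), (_Y, _Y)),
    "vertebral_line":         ((_Y, _Y), (_Y, _Y), (_Y, _Y), (_M, _M), (_Y, _M)),
    "throat_not_immaculate":  ((_M, _M), (_M, _M), (_Y, _Y), (_M, _Y), (_N, _Y)),
    "melanistic_belly":       ((_M, _Y), (_N, _M), (_N, _Y), (_N, _N), (_N, _Y)),
    "ringed_ventral_tail":    ((_M, _M), (_M, _Y), (_N, _N), (_M, _Y), (_M, _N)),
    "antehumeral_fold":       ((_Y, _Y), (_Y, _Y), (_Y, _Y), (_Y, _Y), (_Y, _Y)),
    "neck_folds":             ((_Y, _Y), (_Y, _Y), (_Y, _Y), (_Y, _Y), (_Y, _Y)),
}


def character_applicability() -> dict:
    return {
        ch: ("adult-males-only" if ch in ADULT_MALE_CHARACTERS else "all")
        for ch in _TABLE1
    }


def _states_for(freq: float, n: int) -> np.ndarray:
    """Deterministic state vector with round(freq * n) ones.

    Mixed published cells pin the count of each state, not which
    individual carries it; ones are assigned to the first individuals so
    reconstruction is reproducible.  A mixed cell always yields at least
    one individual of each state.
    """
    ones = int(round(freq * n))
    if 0.0 < freq < 1.0:
        ones = min(max(ones, 1), n - 1)
    return np.array([1.0] * ones + [0.0] * (n - ones))


def walkeri_character_matrix(males_only: bool = False) -> CharacterMatrix:
    """The focal samples' binary character matrix, one row per individual.

    With ``males_only`` the matrix is restricted to adult males — the
    stratum on which the pore/ventral-pattern characters are scored.
    """
    rows = []
    for taxon in TAXA:
        n_f, n_m = DISCRETE_N[taxon]
        for sex, n in (("female", n_f), ("male", n_m)):
            if males_only and sex == "female":
                continue
            block = {
                "id": [f"{taxon}_{sex[0]}{i + 1}" for i in range(n)],
                "taxon": [taxon] * n,
                "sex": [sex] * n,
                "age_class": ["adult"] * n,
            }
            ti = TAXA.index(taxon)
            for ch, cells in _TABLE1.items():
                freq = cells[ti][0 if sex == "female" else 1]
                block[ch] = _states_for(freq, n)
            rows.append(pd.DataFrame(block))
    data = pd.concat(rows, ignore_index=True)
    matrix = CharacterMatrix(data, character_applicability())
    return matrix.apply_applicability()


def _load_csv(name: str) -> list[ContinuousSummary]:
    with resources.as_file(resources.files("intdelim.data") / name) as p:
        return read_continuous_summary(p)


def meristic_summaries() -> list[ContinuousSummary]:
    """Scale-count (meristic) summaries of the five focal samples."""
    return _load_csv("meristic_summaries.csv")


def morphometric_summaries() -> list[ContinuousSummary]:
    """Morphometric (mm) summaries of the five focal samples."""
    return _load_csv("morphometric_summaries.csv")


def all_summaries() -> list[ContinuousSummary]:
    return meristic_summaries() + morphometric_summaries()
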