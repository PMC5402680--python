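"""Shipped fixtures: the four in-scope biomarkers and named subject presets.

The biomarker table (``data/biomarkers.tsv``) carries molecular weight and
brain/skin tissue concentrations; subject presets carry the neonate/adult
volumes, the sex-specific GFR coefficients resolved downstream, and the
pigmentation-dependent skin S100B concentration.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Mapping

import pandas as pd

from .errors import InvalidInputError
from .physiology import Biomarker, SubjectProfile

# Friendly aliases accepted in configs and on the CLI, case-insensitive.
_BIOMARKER_ALIASES = {
    "s100b": "s100b_monomer",
    "s100b-monomer": "s100b_monomer",
    "s100b-dimer": "s100b_dimer",
    "s100b_homodimer": "s100b_dimer",
    "uch-l1": "uchl1",
    "uchl-1": "uchl1",
}


@lru_cache(maxsize=1)
def load_biomarkers() -> Mapping[str, Biomarker]:
    """Load the shipped biomarker table into Biomarker objects, keyed by name."""
    with resources.files("neuropk").joinpath("data/biomarkers.tsv").open("r") as fh:
        table = pd.read_csv(fh, sep="\t")
    markers = {}
    for row in table.itertuples(index=False):
        markers[row.name] = Biomarker(
            name=row.name,
            molecular_weight=float(row.molecular_weight_da),
            brain_conc=float(row.brain_conc_ng_ml),
            organ_concs={"skin": float(row.skin_conc_ng_ml)},
        )
    return markers


def get_biomarker(name: str) -> Biomarker:
    """Look up a shipped biomarker by name or alias (case-insensitive)."""
    key = name.strip().lower().replace(" ", "_")
    key = _BIOMARKER_ALIASES.get(key, key)
    markers = load_biomarkers()
    if key not in markers:
        raise InvalidInputError(
            f"unknown biomarker {name!r}; shipped markers: {', '.join(sorted(markers))}"
        )
    return markers[key]


@lru_cache(maxsize=1)
def subject_presets() -> Mapping[str, SubjectProfile]:
    """Named subject presets selectable by key in configs and on the CLI."""
    adult_male = SubjectProfile(
        age_class="adult",
        sex="male",
        brain_volume=1.42,
        blood_volume=6.0,
        height=1.8,
        weight=80.0,
    )
    presets = {
        "neonate": SubjectProfile(
            age_class="neonate",
            sex="male",
            brain_volume=0.42,
            blood_volume=0.28,
            height=0.5,
            weight=3.5,
            body_surface_area=0.25,
        ),
        "adult_male": adult_male,
        "adult_female": SubjectProfile(
            age_class="adult",
            sex="female",
            brain_volume=1.05,
            blood_volume=6.0,
            height=1.65,
            weight=65.0,
        ),
        "adult_male_aa": SubjectProfile(
            age_class="adult",
            sex="male",
            race="african_american",
            brain_volume=1.42,
            blood_volume=6.0,
            height=1.8,
            weight=80.0,
        ),
        # Pigmentation arms: identical anatomy, differing skin S100B content.
        "light_skin": adult_male,  # skin_marker_conc defaults to 0.288 ng/ml
        "dark_skin": SubjectProfile(
            age_class="adult",
            sex="male",
            brain_volume=1.42,
            blood_volume=6.0,
            height=1.8,
            weight=80.0,
            skin_marker_conc=2.0,
        ),
    }
    return presets


def get_preset(name: str) -> SubjectProfile:
    """Look up a subject preset by key."""
    presets = subject_presets()
    key = name.strip().lower()
    if key not in presets:
        raise InvalidInputError(
            f"unknown subject preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[key]
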