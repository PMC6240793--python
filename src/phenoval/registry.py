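"""Named code sets over claims coding systems (ICD-9-CM, ICD-10-CM, CPT).

A computable phenotype is defined against *concepts* (AMI, PCI, diabetes, ...)
rather than raw codes; each concept maps to one or more :class:`CodeSet`
objects, one per coding system.  The registry resolves a claim's
``(code, code_system)`` pair to the set of concepts it evidences.

The default code lists shipped here are small, representative examples of
the code families a claims analyst would use for each concept.  They make
no claim of matching any production phenotype's lists and every set is
overridable from a YAML document (see :func:`load_codesets`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

CODE_SYSTEMS = ("ICD9CM", "ICD10CM", "CPT")

# Inclusion concepts (qualifying cardiac history)
AMI = "AMI"
PCI = "PCI"
CABG = "CABG"
CAD = "CAD"

# Enrichment concepts resolvable from diagnosis codes
DIABETES = "diabetes"
CEREBROVASCULAR = "cerebrovascular_disease"
PAD = "peripheral_arterial_disease"
HEART_FAILURE = "heart_failure"
THREE_VESSEL_CAD = "three_vessel_cad"

# Exclusion concepts
SIGNIFICANT_BLEEDING = "significant_bleeding"
GI_BLEED = "gi_bleed"

#: every concept the eligibility phenotype needs; a registry missing one of
#: these cannot drive the phenotype and is rejected at load time.
REQUIRED_CONCEPTS = (
    AMI,
    PCI,
    CABG,
    CAD,
    DIABETES,
    CEREBROVASCULAR,
    PAD,
    HEART_FAILURE,
    THREE_VESSEL_CAD,
    SIGNIFICANT_BLEEDING,
    GI_BLEED,
)

INCLUSION_CONCEPTS = (AMI, PCI, CABG, CAD)
EXCLUSION_CONCEPTS = (SIGNIFICANT_BLEEDING, GI_BLEED)

#: the 11 risk-enrichment factor labels used throughout the package
ENRICHMENT_FACTORS = (
    "age_ge_65",
    "creatinine_ge_1_5",
    "diabetes",
    "three_vessel_cad",
    "cerebrovascular_disease",
    "peripheral_arterial_disease",
    "lvef_lt_50",
    "heart_failure",
    "sbp_ge_140_12mo",
    "ldl_ge_130_12mo",
    "current_smoker",
)


class CodesetError(ValueError):
    """Raised for malformed or incomplete codeset configuration."""


@dataclass(frozen=True)
class CodeSet:
    """A set of codes from one coding system evidencing one concept.

    ``match_mode`` is ``"prefix"`` for ICD families (the standard claims
    practice: ``I21`` matches ``I21.09``) and ``"exact"`` for CPT.
    """

    concept_name: str
    code_system: str
    codes: frozenset[str]
    match_mode: str = "prefix"

    def __post_init__(self) -> None:
        if self.code_system not in CODE_SYSTEMS:
            raise CodesetError(
                f"unknown code_system {self.code_system!r} for concept "
                f"{self.concept_name!r}; expected one of {CODE_SYSTEMS}"
            )
        if not self.codes:
            raise CodesetError(f"empty code list for concept {self.concept_name!r}")
        if self.match_mode not in ("exact", "prefix"):
            raise CodesetError(f"match_mode must be 'exact' or 'prefix', got {self.match_mode!r}")

    def matches(self, code: str) -> bool:
        code = code.strip().upper().replace(".", "")
        if self.match_mode == "exact":
            return code in self._normalized()
        return any(code.startswith(p) for p in self._normalized())

    def _normalized(self) -> frozenset[str]:
        return frozenset(c.strip().upper().replace(".", "") for c in self.codes)


@dataclass
class CodeSetRegistry:
    """Concept → per-system code sets, with vectorized claim matching."""

    codesets: list[CodeSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for cs in self.codesets:
            key = (cs.concept_name, cs.code_system)
            if key in seen:
                raise CodesetError(
                    f"duplicate codeset for concept {cs.concept_name!r} "
                    f"in system {cs.code_system!r}"
                )
            seen.add(key)

    @property
    def concepts(self) -> tuple[str, ...]:
        out: list[str] = []
        for cs in self.codesets:
            if cs.concept_name not in out:
                out.append(cs.concept_name)
        return tuple(out)

    def require(self, concepts: Iterable[str] = REQUIRED_CONCEPTS) -> "CodeSetRegistry":
        missing = [c for c in concepts if c not in self.concepts]
        if missing:
            raise CodesetError(f"registry is missing required concept(s): {', '.join(missing)}")
        return self

    def match(self, code: str, code_system: str) -> frozenset[str]:
        """Concepts evidenced by a single (code, system) pair."""
        hits = {
            cs.concept_name
            for cs in self.codesets
            if cs.code_system == code_system and cs.matches(code)
        }
        return frozenset(hits)

    def match_claims(self, claims: pd.DataFrame, concepts: Iterable[str] | None = None) -> pd.DataFrame:
        """Explode a claims table into (claim row, concept) hit rows.

        ``claims`` needs ``code`` and ``code_system`` columns; all other
        columns are carried through.  Returns one row per (claim, concept)
        hit with a ``concept`` column appended.  Vectorized so that cohorts
        of tens of thousands of patients phenotype in seconds.
        """
        wanted = set(concepts) if concepts is not None else None
        if claims.empty:
            return claims.assign(concept=pd.Series(dtype=object)).iloc[0:0]
        norm = (
            claims["code"].astype(str).str.strip().str.upper().str.replace(".", "", regex=False)
        )
        pieces: list[pd.DataFrame] = []
        for cs in self.codesets:
            if wanted is not None and cs.concept_name not in wanted:
                continue
            sysmask = claims["code_system"].to_numpy() == cs.code_system
            if not sysmask.any():
                continue
            if cs.match_mode == "exact":
                hit = norm.isin(cs._normalized()).to_numpy()
            else:
                hit = np.zeros(len(claims), dtype=bool)
                for prefix in cs._normalized():
                    hit |= norm.str.startswith(prefix).to_numpy()
            rows = claims[sysmask & hit]
            if len(rows):
                pieces.append(rows.assign(concept=cs.concept_name))
        if not pieces:
            return claims.assign(concept=pd.Series(dtype=object)).iloc[0:0]
        return pd.concat(pieces, ignore_index=True)


def _registry_from_mapping(doc: Mapping) -> CodeSetRegistry:
    concepts = doc.get("concepts")
    if not isinstance(concepts, Mapping) or not concepts:
        raise CodesetError("codeset document must have a non-empty 'concepts' mapping")
    codesets: list[CodeSet] = []
    for name, systems in concepts.items():
        if not isinstance(systems, Mapping) or not systems:
            raise CodesetError(f"concept {name!r} must map code systems to code lists")
        for system, spec in systems.items():
            if isinstance(spec, Mapping):
                codes = spec.get("codes", [])
                mode = spec.get("match_mode", "exact" if system == "CPT" else "prefix")
            else:
                codes = spec
                mode = "exact" if system == "CPT" else "prefix"
            codesets.append(
                CodeSet(
                    concept_name=str(name),
                    code_system=str(system),
                    codes=frozenset(str(c) for c in codes),
                    match_mode=str(mode),
                )
            )
    return CodeSetRegistry(codesets)


def load_codesets(source) -> CodeSetRegistry:
    """Load a codeset registry from a YAML document.

    ``source`` may be a path, an open file, a YAML string, or an already
    parsed mapping.  The document shape is::

        concepts:
          AMI:
            ICD10CM: [I21, I22, I25.2]
            ICD9CM: ["410", "412"]
          PCI:
            CPT: ["92920", "92928"]

    Every concept in :data:`REQUIRED_CONCEPTS` must be present.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text, "r", encoding="utf-8") as fh:
                    text = fh.read()
            elif "\n" not in text:
                try:
                    with open(text, "r", encoding="utf-8") as fh:
                        text = fh.read()
                except OSError:
                    pass
        doc = yaml.safe_load(text)
        if not isinstance(doc, Mapping):
            raise CodesetError("codeset YAML did not parse to a mapping")
    return _registry_from_mapping(doc).require()


# Representative default code families per concept. ICD prefixes; CPT exact.
# Chosen to be mutually non-overlapping across concepts so that e.g. a
# history-of-MI code never also reads as chronic CAD.
_DEFAULT_CONCEPTS: dict[str, dict[str, list[str]]] = {
    AMI: {
        "ICD10CM": ["I21", "I22", "I25.2"],  # acute MI + old-MI history code
        "ICD9CM": ["410", "412"],
    },
    PCI: {
        "CPT": ["92920", "92924", "92928", "92933", "92937", "92941", "92943"],
        "ICD10CM": ["Z98.61"],  # angioplasty status
        "ICD9CM": ["V45.82", "00.66", "36.06", "36.07"],
    },
    CABG: {
        "CPT": ["33510", "33511", "33512", "33533", "33534", "33535", "33536"],
        "ICD10CM": ["Z95.1"],  # aortocoronary bypass status
        "ICD9CM": ["V45.81", "36.1"],
    },
    CAD: {
        # chronic ischemic heart disease / atherosclerosis; excludes I25.2
        # (old MI) and I25.84/three-vessel marker so concepts stay disjoint
        "ICD10CM": ["I25.1", "I25.5", "I25.9"],
        "ICD9CM": ["414.0", "414.8", "414.9"],
    },
    DIABETES: {
        "ICD10CM": ["E10", "E11"],
        "ICD9CM": ["250"],
    },
    CEREBROVASCULAR: {
        "ICD10CM": ["I63", "I65", "I66", "I67", "I69", "G45"],
        "ICD9CM": ["433", "434", "435", "438"],
    },
    PAD: {
        "ICD10CM": ["I70.2", "I73.9"],
        "ICD9CM": ["440.2", "443.9"],
    },
    HEART_FAILURE: {
        "ICD10CM": ["I50"],
        "ICD9CM": ["428"],
    },
    THREE_VESSEL_CAD: {
        # no standard administrative code exists; representative stand-in
        "ICD10CM": ["I25.84"],
        "ICD9CM": ["414.4"],
    },
    SIGNIFICANT_BLEEDING: {
        "ICD10CM": ["D62", "I62", "R58"],
        "ICD9CM": ["285.1", "432", "459.0"],
    },
    GI_BLEED: {
        "ICD10CM": ["K25.0", "K92.0", "K92.1", "K92.2"],
        "ICD9CM": ["578"],
    },
}


def default_registry() -> CodeSetRegistry:
    """Registry with the packaged representative code lists."""
    return _registry_from_mapping({"concepts": _DEFAULT_CONCEPTS}).require()


def default_codesets_yaml() -> str:
    """The default codesets as a YAML document (for config scaffolding)."""
    return yaml.safe_dump({"concepts": _DEFAULT_CONCEPTS}, sort_keys=False)
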