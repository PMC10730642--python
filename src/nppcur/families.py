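"""Motif-based classification of mature active peptides into families.

The seven families handled here -- LWamide, APGWamide, RPCH/AKH1-4, ACP,
CRZ and GnRH -- share a conserved scaffold (a tryptophan anchor near
position 8, the amide-donor glycine and the flanking dibasic dyads) and
differ in a small number of positional features: phenylalanine at
position 4 in the RPCH/AKH core, the residue immediately after the
tryptophan (G in AKH2, Q in AKH3), the Gln-Tyr and Thr-Asn-Gly motifs of
corazonin, and the C-terminal ...GW / ...LW signatures of APGWamide and
LWamide.

Rules are declarative predicate lists evaluated in a fixed order; the
first fully matching rule wins.  The most feature-rich families are
tested first so the short generic C-terminal rules cannot shadow them.
Positions in predicates are 1-based from the mature peptide N-terminus.
An N-terminal Q is treated as equivalent to pyroglutamate; no sequence
edit is made.

RPCH and AKH1 are not separable on the sequence features alone; the
classifier returns the merged call ``RPCH/AKH1`` and refines it to
``RPCH`` when a supplied lineage places the species in Crustacea, the
only taxon expressing RPCH.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .purge import ActivePeptide, PrecursorAnnotation

UNCLASSIFIED = "unclassified"


# ---------------------------------------------------------------------------
# predicate engine


def _eval(pred: dict, pep: str, amidated: bool) -> bool:
    kind = pred["type"]
    if kind == "amidated":
        return amidated
    if kind == "len_between":
        return pred["lo"] <= len(pep) <= pred["hi"]
    if kind == "res_at":  # 1-based position
        pos = pred["pos"]
        return len(pep) >= pos and pep[pos - 1] == pred["aa"]
    if kind == "contains":
        return pred["motif"] in pep
    if kind == "ends_with":
        return pep.endswith(pred["motif"])
    if kind == "not_contains_res":
        return pred["aa"] not in pep
    if kind == "res_from":  # residue occurs at 1-based position >= pos
        return pred["aa"] in pep[pred["pos"] - 1 :]
    if kind == "flanked":  # before ... motif ... after, in order
        i = pep.find(pred["motif"])
        if i < 0:
            return False
        return pred["before"] in pep[:i] and pred["after"] in pep[i + len(pred["motif"]) :]
    if kind == "any":
        return any(_eval(p, pep, amidated) for p in pred["preds"])
    if kind == "not_all":
        return not all(_eval(p, pep, amidated) for p in pred["preds"])
    raise ValueError(f"unknown predicate type {kind!r}")


def _name(pred: dict) -> str:
    kind = pred["type"]
    args = ",".join(
        str(pred[k]) for k in sorted(pred) if k not in ("type", "preds")
    )
    return f"{kind}({args})" if args else kind


@dataclass(frozen=True)
class FamilyRule:
    """A family name plus its ordered predicate tests."""

    family: str
    predicates: tuple

    def matches(self, pep: str, amidated: bool) -> Optional[list]:
        fired = []
        for pred in self.predicates:
            if not _eval(pred, pep, amidated):
                return None
            fired.append(_name(pred))
        return fired


@dataclass(frozen=True)
class FamilyCall:
    family: str
    matched_features: tuple = ()


# Ordered rule set.  Feature-rich families first; the AKH4 rule is the
# in-supergroup exclusion (AKH-like length, W anchor, pyroglutamate
# start, but a non-canonical arrangement around the tryptophan).
FAMILY_RULES: tuple = (
    FamilyRule(
        "RPCH/AKH1",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 8, "hi": 8},
            {"type": "res_at", "pos": 4, "aa": "F"},
            {"type": "res_at", "pos": 8, "aa": "W"},
        ),
    ),
    FamilyRule(
        "AKH2",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 9, "hi": 9},
            {"type": "res_at", "pos": 4, "aa": "F"},
            {"type": "res_at", "pos": 8, "aa": "W"},
            {"type": "res_at", "pos": 9, "aa": "G"},
        ),
    ),
    FamilyRule(
        "AKH3",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 9, "hi": 10},
            {"type": "res_at", "pos": 4, "aa": "F"},
            {"type": "res_at", "pos": 8, "aa": "W"},
            {"type": "res_at", "pos": 9, "aa": "Q"},
        ),
    ),
    FamilyRule(
        "AKH4",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 8, "hi": 10},
            {"type": "res_at", "pos": 1, "aa": "Q"},
            {"type": "contains", "motif": "W"},
            {"type": "not_contains_res", "aa": "P"},
            {
                "type": "not_all",
                "preds": (
                    {"type": "res_at", "pos": 4, "aa": "F"},
                    {"type": "res_at", "pos": 8, "aa": "W"},
                ),
            },
        ),
    ),
    FamilyRule(
        "ACP",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 10, "hi": 12},
            {"type": "res_at", "pos": 1, "aa": "Q"},
            {"type": "res_at", "pos": 4, "aa": "F"},
            {"type": "res_from", "pos": 8, "aa": "W"},
        ),
    ),
    FamilyRule(
        "CRZ",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 10, "hi": 13},
            {"type": "contains", "motif": "QY"},
            {"type": "flanked", "motif": "QY", "before": "F", "after": "S"},
            {
                "type": "any",
                "preds": (
                    {"type": "contains", "motif": "TNG"},
                    {"type": "ends_with", "motif": "TN"},
                ),
            },
        ),
    ),
    FamilyRule(
        "GnRH",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 9, "hi": 12},
            {"type": "res_at", "pos": 1, "aa": "G"},
            {"type": "contains", "motif": "W"},
        ),
    ),
    FamilyRule(
        "APGWamide",
        (
            {"type": "amidated"},
            {"type": "len_between", "lo": 4, "hi": 40},
            {"type": "ends_with", "motif": "GW"},
            {"type": "not_contains_res", "aa": "L"},
        ),
    ),
    FamilyRule(
        "LWamide",
        (
            {"type": "amidated"},
            {"type": "ends_with", "motif": "W"},
            {"type": "contains", "motif": "L"},
        ),
    ),
)

FAMILY_NAMES = tuple(r.family for r in FAMILY_RULES)

_CRUSTACEAN_MARKERS = ("crustacea", "malacostraca", "branchiopoda", "decapoda")


def _is_crustacean(lineage) -> bool:
    return any(
        marker in str(name).lower()
        for _, name in (lineage or ())
        for marker in _CRUSTACEAN_MARKERS
    )


def classify_family(
    peptide: str, amidated: bool, lineage: Optional[Sequence] = None
) -> FamilyCall:
    """Classify one mature peptide; first matching rule wins.

    ``lineage`` (ordered rank, name pairs) is only consulted to refine
    the merged RPCH/AKH1 call: a crustacean lineage yields RPCH.
    """
    if not peptide:
        raise ValueError("empty peptide")
    for rule in FAMILY_RULES:
        fired = rule.matches(peptide, amidated)
        if fired is not None:
            family = rule.family
            if family == "RPCH/AKH1" and _is_crustacean(lineage):
                family = "RPCH"
                fired = fired + ["crustacean_lineage"]
            return FamilyCall(family, tuple(fired))
    return FamilyCall(UNCLASSIFIED, ())


#: protostome GnRH reference length (deuterostome forms run two shorter)
_GNRH_PROTOSTOME_LEN = 12


def classify_gnrh_lineage(peptide: str) -> str:
    """Subtype a GnRH-called peptide: protostome, deuterostome, ambiguous.

    Protostome forms keep the full length with G at position 1 and S at
    position 5; deuterostome forms are two residues shorter, sharing the
    leading glycine, the tryptophan anchor and a proline.
    """
    n = len(peptide)
    if n == _GNRH_PROTOSTOME_LEN and peptide[0] == "G" and n >= 5 and peptide[4] == "S":
        return "protostome"
    if (
        n == _GNRH_PROTOSTOME_LEN - 2
        and peptide[0] == "G"
        and "W" in peptide
        and "P" in peptide
    ):
        return "deuterostome"
    return "ambiguous"


def extract_active_peptides(annotation: PrecursorAnnotation) -> list[ActivePeptide]:
    """Mature peptides of an annotated precursor.

    Peptides are the inter-site segments between productive cleavage
    sites, trimmed of the amide-donor glycine; they are computed during
    the structural screen and carried on the annotation.
    """
    return list(annotation.peptides)


def rules_to_json() -> str:
    """The frozen rule set as a JSON document (order-preserving)."""
    doc = [
        {"family": r.family, "predicates": list(r.predicates)}
        for r in FAMILY_RULES
    ]
    return json.dumps(doc, indent=2)


def rules_from_json(text: str) -> tuple:
    doc = json.loads(text)
    return tuple(
        FamilyRule(d["family"], tuple(d["predicates"])) for d in doc
    )
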