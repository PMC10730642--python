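"""Labeled synthetic inputs for every pipeline stage.

The generator emulates the candidate pool the curation pipeline sees: a
mix of well-formed precursors (signal peptide, one or more family
peptides each followed by the amide-donor glycine and a dibasic dyad,
then a related-peptide tail) and records carrying exactly one structural
defect (no signal, no dyads, no amide glycine, or truncation).  Family
peptides are canonical rule-satisfying templates, one per family,
optionally point-mutated.  CDS sequences are produced by reverse
translation with uniform synonymous codon choice.

All randomness flows from a single seed through numpy's default
generator (PCG64), so output is byte-identical across runs and
platforms.  Validity is assigned by stratification (exactly
``round(n * p_valid)`` valid records) so count assertions are exact; a
Bernoulli mode exists for statistical tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .core_io import PrecursorRecord
from .phylo import PhyloNode, PhyloTree
from .purge import DYADS

STANDARD_20 = "ACDEFGHIKLMNPQRSTVWY"

#: canonical rule-satisfying active-peptide template per family
FAMILY_TEMPLATES = {
    "APGWamide": "APGW",
    "LWamide": "GSGSLW",
    "RPCH/AKH1": "QLNFSPGW",
    "AKH2": "QLNFSTGWG",
    "AKH3": "QLNFSTGWQ",
    "AKH4": "QVNWGGSTA",
    "ACP": "QITFSRSWGA",
    "CRZ": "QTFQYSRGWTN",
    "GnRH": "GNDWSTAWQPGS",  # protostome-style; a deuterostome variant below
}
GNRH_DEUTEROSTOME_TEMPLATE = "GHWSYALRPG"

INVALIDATION_MODES = ("drop_signal", "drop_dyad", "drop_amide_G", "truncate")

_HYDROPHOBIC_POOL = "AILMFV"
_POLAR_POOL = "DENSQTG"
_MIN_TOTAL_LEN = 48

# standard-code reverse translation table, deterministic codon order
_fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
_BACK_TABLE: dict = {}
for codon, aa in sorted(_fwd.items()):
    _BACK_TABLE.setdefault(aa, []).append(codon)


@dataclass
class SyntheticConfig:
    n_records: int = 100
    p_valid: float = 0.4
    family_mix: dict = field(default_factory=lambda: {f: 1.0 for f in FAMILY_TEMPLATES})
    n_copies_range: tuple = (1, 3)
    mutation_rate: float = 0.0
    invalidation_weights: dict = field(
        default_factory=lambda: {m: 1.0 for m in INVALIDATION_MODES}
    )
    bernoulli: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_valid <= 1.0:
            raise ValueError("p_valid must be in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if sum(self.family_mix.values()) <= 0:
            raise ValueError("family_mix weights must sum to a positive value")


@dataclass(frozen=True)
class TruthLabel:
    record_id: str
    is_valid: bool
    family: str
    copy_count: int
    corruption: Optional[str] = None


def _weighted_choice(rng, weights: dict) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _reverse_translate(aa: str, rng) -> str:
    return "".join(
        _BACK_TABLE[c][rng.integers(len(_BACK_TABLE[c]))] for c in aa
    )


def _rand_str(rng, pool: str, length: int) -> str:
    return "".join(pool[i] for i in rng.integers(len(pool), size=length))


def _build_valid(rng, template: str, k: int) -> str:
    signal = "M" + _rand_str(rng, _HYDROPHOBIC_POOL, 14)
    dyad = DYADS[rng.integers(len(DYADS))]
    body = "G" + dyad
    for _ in range(k):
        body += template + "G" + DYADS[rng.integers(len(DYADS))]
    cur = len(signal) + len(body)
    filler = _rand_str(rng, _POLAR_POOL, max(12, _MIN_TOTAL_LEN - cur))
    return signal + body + filler


def _build_record_aa(rng, family: str, template: str, k: int, corruption):
    if corruption is None:
        return _build_valid(rng, template, k)
    if corruption == "drop_signal":
        prefix = "M" + _rand_str(rng, _POLAR_POOL, 29)
        body = "G" + DYADS[rng.integers(len(DYADS))]
        for _ in range(k):
            body += template + "G" + DYADS[rng.integers(len(DYADS))]
        cur = len(prefix) + len(body)
        return prefix + body + _rand_str(rng, _POLAR_POOL, max(12, _MIN_TOTAL_LEN - cur))
    if corruption == "drop_dyad":
        signal = "M" + _rand_str(rng, _HYDROPHOBIC_POOL, 14)
        body = "".join(template + "G" for _ in range(k))
        cur = len(signal) + len(body)
        return signal + body + _rand_str(rng, _POLAR_POOL, max(12, _MIN_TOTAL_LEN - cur))
    if corruption == "drop_amide_G":
        tpl = template[:-1] if template.endswith("G") else template
        signal = "M" + _rand_str(rng, _HYDROPHOBIC_POOL, 14)
        body = DYADS[rng.integers(len(DYADS))]
        for _ in range(k):
            body += tpl + DYADS[rng.integers(len(DYADS))]
        cur = len(signal) + len(body)
        return signal + body + _rand_str(rng, _POLAR_POOL, max(12, _MIN_TOTAL_LEN - cur))
    if corruption == "truncate":
        return _build_valid(rng, template, k)[:30]
    raise ValueError(f"unknown corruption mode {corruption!r}")


def generate_precursors(config: SyntheticConfig):
    """Generate (records, truth) under the config's seed.

    Valid records follow the canonical precursor anatomy; invalid
    records carry exactly one sampled corruption.  Every record gets a
    consistent CDS by reverse translation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    if config.bernoulli:
        valid_mask = rng.random(n) < config.p_valid
    else:
        n_valid = round(n * config.p_valid)
        valid_mask = np.zeros(n, dtype=bool)
        valid_mask[rng.permutation(n)[:n_valid]] = True

    records, truth = [], []
    for idx in range(n):
        rid = f"SYN{idx:05d}"
        family = _weighted_choice(rng, config.family_mix)
        template = FAMILY_TEMPLATES[family]
        if family == "GnRH" and rng.random() < 0.5:
            template = GNRH_DEUTEROSTOME_TEMPLATE
        lo, hi = config.n_copies_range
        k = int(rng.integers(lo, hi + 1))
        corruption = (
            None
            if valid_mask[idx]
            else _weighted_choice(rng, config.invalidation_weights)
        )
        aa = _build_record_aa(rng, family, template, k, corruption)
        rec = PrecursorRecord(
            record_id=rid, aa_seq=aa, cds_seq=_reverse_translate(aa, rng)
        )
        if config.mutation_rate > 0:
            rec = mutate_precursor(
                rec, config.mutation_rate, seed=int(rng.integers(2**31))
            )
        records.append(rec)
        truth.append(
            TruthLabel(rid, bool(valid_mask[idx]), family, k, corruption)
        )
    return records, truth


def mutate_precursor(record: PrecursorRecord, rate: float, seed: int) -> PrecursorRecord:
    """Per-residue substitution among the other 19 standard residues.

    The CDS is kept consistent by re-encoding each mutated residue with a
    uniformly chosen synonymous codon.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = list(record.aa_seq)
    cds = list(record.cds_seq) if record.cds_seq else None
    for i, c in enumerate(chars):
        if rng.random() < rate:
            options = [x for x in STANDARD_20 if x != c]
            new = options[rng.integers(len(options))] if c in STANDARD_20 else c
            if new != c:
                chars[i] = new
                if cds is not None:
                    codon = _BACK_TABLE[new][rng.integers(len(_BACK_TABLE[new]))]
                    cds[3 * i : 3 * i + 3] = codon
    return PrecursorRecord(
        record_id=record.record_id,
        aa_seq="".join(chars),
        species=record.species,
        lineage=record.lineage,
        cds_seq="".join(cds) if cds is not None else None,
        family_claim=record.family_claim,
    )


# ---------------------------------------------------------------------------
# tree fixtures


def _random_binary_tree(rng, n_leaves: int) -> PhyloTree:
    nodes = [PhyloNode(label=f"L{i + 1}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = PhyloNode(children=[nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return PhyloTree(nodes[0])


def _nni_candidates(tree: PhyloTree):
    out = []

    def walk(node):
        for child in node.children:
            if not child.is_leaf:
                out.append((node, child))
            walk(child)

    walk(tree.root)
    return out


def _apply_random_nni(tree: PhyloTree, rng) -> None:
    candidates = _nni_candidates(tree)
    if not candidates:
        return
    parent, v = candidates[rng.integers(len(candidates))]
    siblings = [c for c in parent.children if c is not v]
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    parent.children[parent.children.index(s)] = c
    v.children[v.children.index(c)] = s


def generate_tree_pair(n_leaves: int, k_nni: int, seed: int):
    """A random binary tree and a k-NNI neighbour of it.

    Each nearest-neighbour interchange alters at most one split per
    tree, so RF(t1, t2) <= 2 * k_nni.
    """
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves")
    if k_nni < 0:
        raise ValueError("k_nni must be non-negative")
    rng = np.random.default_rng(seed)
    t1 = _random_binary_tree(rng, n_leaves)
    t2 = t1.copy()
    for _ in range(k_nni):
        _apply_random_nni(t2, rng)
    return t1, t2
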