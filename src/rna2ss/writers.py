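"""Serialization of annotated secondary structure.

CT and BPSEQ are per-residue single-partner formats: they carry the
slot-0 (secondary) partner and cannot express base triples, so extra
partners are omitted with a logged count (BPSEQ additionally appends them
as ``# TRIPLE i j`` comment lines so no pairing is lost).  Dot-bracket
renders pseudoknot layers with successive bracket alphabets.  JSON is the
lossless format of record.

All files are UTF-8 with LF line endings.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .helix_topology import Helix, TopologyAnnotation, SECONDARY
from .pair_geometry import BasePair

logger = logging.getLogger(__name__)

__all__ = [
    "SecondaryStructureRecord",
    "CtFormatError",
    "write_ct",
    "read_ct",
    "write_bpseq_extended",
    "write_dotbracket",
    "write_json",
    "read_json",
    "BRACKET_ALPHABETS",
]

SCHEMA_VERSION = "1.0"

BRACKET_ALPHABETS: list[tuple[str, str]] = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")] + [
    (c, c.lower()) for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
]


class CtFormatError(Exception):
    """Malformed CT file (asymmetry, count mismatch, bad fields)."""


@dataclass
class SecondaryStructureRecord:
    """The serializable, layered per-residue pairing table.

    ``partners[r]`` (keyed by 1-based residue index) is the ordered partner
    list of residue r: slot 0 is the secondary pair (or absent when r is
    unpaired); later slots are base-triple partners.  ``pairs`` and
    ``helices`` carry the full annotation for lossless JSON output.
    """

    sequence: str
    partners: dict[int, list[int]]
    pairs: list[BasePair] = field(default_factory=list)
    helices: list[Helix] = field(default_factory=list)
    annotation: TopologyAnnotation = field(default_factory=TopologyAnnotation)
    domain_of: list[str] = field(default_factory=list)
    labels: dict[int, str] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    title: str = "rna2ss"

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def slot0(self, r: int) -> int:
        lst = self.partners.get(r, [])
        return lst[0] if lst else 0

    def mutual_slot0(self, r: int) -> int:
        """Slot-0 partner only when the relation is mutual.

        A residue whose only pairing is a tertiary triple partner has that
        partner in its slot 0, but the partner's own slot 0 points into a
        helix; flat per-residue formats can only carry the mutual subset.
        """
        j = self.slot0(r)
        return j if j and self.slot0(j) == r else 0

    @property
    def helix_of(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for h in self.helices:
            for r in h.residues():
                out[r] = h.helix_id
        return out

    def validate(self) -> None:
        for r, plist in self.partners.items():
            for q in plist:
                assert r in self.partners.get(q, []), f"partner table asymmetric at {r}/{q}"


def _all_edges(record: SecondaryStructureRecord) -> set[tuple[int, int]]:
    return {
        (min(r, q), max(r, q))
        for r, plist in record.partners.items()
        for q in plist
    }


def _serialized_edges(record: SecondaryStructureRecord) -> set[tuple[int, int]]:
    return {
        (r, record.mutual_slot0(r))
        for r in range(1, record.n_residues + 1)
        if record.mutual_slot0(r) > r
    }


def _extra_pairs(record: SecondaryStructureRecord) -> list[tuple[int, int]]:
    """Pairs a flat single-partner format cannot carry, each listed once."""
    return sorted(_all_edges(record) - _serialized_edges(record))


def write_ct(record: SecondaryStructureRecord, path: str | Path) -> int:
    """Write 6-column CT; returns the number of omitted (beyond-slot-0) pairs.

    Columns: index, base, index-1, index+1, slot-0 partner (0 when
    unpaired), index.  One header line carries the residue count and title.
    """
    n = record.n_residues
    lines = [f"{n} {record.title}"]
    for r in range(1, n + 1):
        nxt = r + 1 if r < n else 0
        lines.append(
            f"{r} {record.sequence[r - 1]} {r - 1} {nxt} {record.mutual_slot0(r)} {r}"
        )
    omitted = _extra_pairs(record)
    if omitted:
        logger.info("CT writer omitted %d pair(s) beyond slot 0", len(omitted))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return len(omitted)


def read_ct(path: str | Path) -> SecondaryStructureRecord:
    """Parse a 6-column CT file back into a slot-0-only record."""
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise CtFormatError(f"{path}: empty file")
    header = lines[0].split()
    try:
        count = int(header[0])
    except (IndexError, ValueError) as exc:
        raise CtFormatError(f"{path}: bad header {lines[0]!r}") from exc
    title = " ".join(header[1:])
    body = lines[1:]
    if len(body) != count:
        raise CtFormatError(
            f"{path}: header declares {count} residues but file has {len(body)} data lines"
        )
    seq: list[str] = []
    partner: dict[int, int] = {}
    for ln_no, ln in enumerate(body, start=2):
        fields = ln.split()
        if len(fields) < 6:
            raise CtFormatError(f"{path}:{ln_no}: expected 6 columns, got {len(fields)}")
        idx, base, partner_idx = int(fields[0]), fields[1], int(fields[4])
        if idx != len(seq) + 1:
            raise CtFormatError(f"{path}:{ln_no}: residue index {idx} out of order")
        seq.append(base)
        partner[idx] = partner_idx
    for i, j in partner.items():
        if j != 0 and partner.get(j, 0) != i:
            line = i + 1
            raise CtFormatError(
                f"{path}:{line}: asymmetric pairing {i}->{j} but {j}->{partner.get(j, 0)}"
            )
    partners = {i: ([j] if j else []) for i, j in partner.items()}
    return SecondaryStructureRecord(sequence="".join(seq), partners=partners, title=title)


def write_bpseq_extended(record: SecondaryStructureRecord, path: str | Path) -> int:
    """Write 3-column BPSEQ plus ``# TRIPLE i j`` trailer lines.

    The trailer preserves partners beyond slot 0 so base triples remain
    visible as pairs of base pairs; returns the trailer pair count.
    """
    lines = []
    for r in range(1, record.n_residues + 1):
        lines.append(f"{r} {record.sequence[r - 1]} {record.mutual_slot0(r)}")
    extras = _extra_pairs(record)
    for i, j in extras:
        lines.append(f"# TRIPLE {i} {j}")
    if extras:
        logger.info("BPSEQ writer annotated %d pair(s) beyond slot 0 as TRIPLE lines", len(extras))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return len(extras)


def _bracket_layers(record: SecondaryStructureRecord) -> dict[tuple[int, int], int]:
    """Assign a bracket layer to every slot-0 pair.

    Helix pairs inherit their helix's pseudoknot layer.  Slot-0 pairs
    outside any helix are placed on the lowest layer >= 1 where they cross
    no already-placed pair.
    """
    helix_layer = record.annotation.layer
    helix_of_pair: dict[tuple[int, int], int] = {}
    for h in record.helices:
        for p in h.pairs:
            helix_of_pair[p.key()] = h.helix_id

    slot0_pairs = sorted(_serialized_edges(record))

    assigned: dict[tuple[int, int], int] = {}
    members: dict[int, list[tuple[int, int]]] = {}
    for key in slot0_pairs:
        hid = helix_of_pair.get(key)
        if hid is not None and hid in helix_layer:
            lay = helix_layer[hid]
            assigned[key] = lay
            members.setdefault(lay, []).append(key)
    def crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[0] < a[1] < b[1] or b[0] < a[0] < b[1] < a[1]
    for key in slot0_pairs:
        if key in assigned:
            continue
        lay = 1
        while any(crosses(key, other) for other in members.get(lay, [])):
            lay += 1
        assigned[key] = lay
        members.setdefault(lay, []).append(key)
    return assigned


def write_dotbracket(record: SecondaryStructureRecord, path: str | Path) -> int:
    """Write sequence + layered dot-bracket structure lines.

    Layer 0 renders as ``()``; higher layers as ``[]``, ``{}``, ``<>``,
    ``Aa`` ...  Pairs beyond the available alphabets and beyond-slot-0
    partners are omitted (logged); returns the omitted count.
    """
    n = record.n_residues
    struct = ["."] * n
    layers = _bracket_layers(record)
    omitted = len(_extra_pairs(record))
    for (i, j), lay in sorted(layers.items()):
        if lay >= len(BRACKET_ALPHABETS):
            omitted += 1
            continue
        op, cl = BRACKET_ALPHABETS[lay]
        struct[i - 1] = op
        struct[j - 1] = cl
    if omitted:
        logger.info("dot-bracket writer omitted %d pair(s)", omitted)
    Path(path).write_text(record.sequence + "\n" + "".join(struct) + "\n", encoding="utf-8")
    return omitted


def _pair_to_dict(p: BasePair) -> dict:
    return {
        "i": p.i,
        "j": p.j,
        "edge_i": p.edge_i,
        "edge_j": p.edge_j,
        "orientation": p.orientation,
        "canonical": p.canonical,
        "origin_distance": p.origin_distance,
        "plane_angle": p.plane_angle,
        "vertical_offset": p.vertical_offset,
        "n_hbonds": p.n_hbonds,
        "borderline": p.borderline,
    }


def write_json(record: SecondaryStructureRecord, path: str | Path) -> None:
    """Lossless dump of the full annotated structure."""
    ann = record.annotation
    payload = {
        "schema_version": SCHEMA_VERSION,
        "title": record.title,
        "sequence": record.sequence,
        "partners": {str(r): v for r, v in sorted(record.partners.items())},
        "pairs": [
            {**_pair_to_dict(p), "role": ann.pair_role.get(p.key(), "tertiary")}
            for p in record.pairs
        ],
        "helices": [
            {
                "helix_id": h.helix_id,
                "pairs": [[p.i, p.j] for p in h.pairs],
                "strand5_range": list(h.strand5_range),
                "strand3_range": list(h.strand3_range),
                "has_defect": h.has_defect,
                "label": h.label,
                "class": ann.helix_class.get(h.helix_id),
                "layer": ann.layer.get(h.helix_id),
            }
            for h in record.helices
        ],
        "crossing_pairs": [list(c) for c in ann.crossing_pairs],
        "domains": record.domain_of,
        "labels": {str(k): v for k, v in sorted(record.labels.items())},
        "params": record.params,
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path: str | Path) -> SecondaryStructureRecord:
    """Rebuild a record from :func:`write_json` output."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    pairs = [
        BasePair(
            i=d["i"], j=d["j"], edge_i=d["edge_i"], edge_j=d["edge_j"],
            orientation=d["orientation"], canonical=d["canonical"],
            origin_distance=d["origin_distance"], plane_angle=d["plane_angle"],
            vertical_offset=d["vertical_offset"], n_hbonds=d["n_hbonds"],
            borderline=d["borderline"],
        )
        for d in data["pairs"]
    ]
    by_key = {(p.i, p.j): p for p in pairs}
    ann = TopologyAnnotation(
        pair_role={(d["i"], d["j"]): d["role"] for d in data["pairs"]},
        crossing_pairs=[tuple(c) for c in data["crossing_pairs"]],
    )
    helices = []
    for hd in data["helices"]:
        h = Helix(
            helix_id=hd["helix_id"],
            pairs=[by_key[tuple(pq)] for pq in hd["pairs"]],
            has_defect=hd["has_defect"],
            label=hd["label"],
        )
        helices.append(h)
        if hd["class"] is not None:
            ann.helix_class[h.helix_id] = hd["class"]
        if hd["layer"] is not None:
            ann.layer[h.helix_id] = hd["layer"]
    return SecondaryStructureRecord(
        sequence=data["sequence"],
        partners={int(k): v for k, v in data["partners"].items()},
        pairs=pairs,
        helices=helices,
        annotation=ann,
        domain_of=data["domains"],
        labels={int(k): v for k, v in data["labels"].items()},
        params=data["params"],
        title=data["title"],
    )
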