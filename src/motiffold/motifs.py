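"""RNA 3D motif descriptors and their topological variants.

A motif descriptor names a recurrent 3D motif (K-turn, GNRA tetraloop,
loop E, ...) and gives IUPAC consensus strings for the sequence segments
that make it up.  Six architectures are supported, one per loop class:

``HL``
    hairpin-loop motif: up to three nested correlated profile pairs
    (L1,R1)..(Lk,Rk) around a final Loop; linear order L1..Lk Loop Rk..R1.
``BL``
    bulge motif: a single strand with the same optional internal
    correlated pairs plus Loop.
``IL``
    internal-loop motif: outer correlated pair (Lo,Ro), inner pair
    (Li,Ri) and two loops; 5'->3' the strands read Lo Loop1 Li / Ri Loop2 Ro.
``J3``/``J4``
    three-/four-way junction motifs: one branch segment between each
    pair of helices (segments may be empty, meaning coaxial stacking).
``BS``
    branch segment: a single-strand motif on one branch of any multiloop.

Descriptor file dialect (one record per line, ``#`` comments)::

    HL GNRA   L1=G Loop=N R1=RA
    IL K-turn Li=GA Ri=GA Loop2=RNN
    J3 groupII S1=A S2=RAA S3=

An empty value means an empty segment (still modeled, so it can absorb
insertions); an absent key means the segment does not exist.

Motifs bounded by more than one helix have topological *variants*
depending on which end carries the external 5'/3' attachment: BL and IL
have two, J3 three, J4 four.  :func:`expand_variants` generates all of
them and merges the redundant ones (identical class and rotated segment
tuple).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

from .alignments import IUPAC

log = logging.getLogger(__name__)

MOTIF_CLASSES = ("HL", "BL", "IL", "J3", "J4", "BS")

#: variants per class before redundancy elimination
VARIANT_COUNTS = {"HL": 1, "BL": 2, "IL": 2, "J3": 3, "J4": 4, "BS": 1}

_MAX_HL_PAIRS = 3  # nesting depth cap for HL/BL correlated profile pairs

_CLASS_KEYS = {
    "HL": {"L1", "L2", "L3", "R1", "R2", "R3", "Loop"},
    "BL": {"L1", "L2", "L3", "R1", "R2", "R3", "Loop"},
    "IL": {"Lo", "Loop1", "Li", "Ri", "Loop2", "Ro"},
    "J3": {"S1", "S2", "S3"},
    "J4": {"S1", "S2", "S3", "S4"},
    "BS": {"S1"},
}
_REQUIRED_KEYS = {
    "HL": {"Loop"},
    "BL": {"Loop"},
    "IL": set(),
    "J3": {"S1", "S2", "S3"},
    "J4": {"S1", "S2", "S3", "S4"},
    "BS": {"S1"},
}


class DescriptorError(ValueError):
    """Raised for malformed motif descriptor records."""


@dataclass(frozen=True)
class MotifDescriptor:
    """A named 3D motif with consensus segment strings."""

    name: str
    motif_class: str
    segments: dict[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise DescriptorError(f"unknown motif class {self.motif_class!r}")
        allowed = _CLASS_KEYS[self.motif_class]
        for key, cons in self.segments.items():
            if key not in allowed:
                raise DescriptorError(
                    f"{self.name}: segment key {key!r} invalid for class {self.motif_class}"
                )
            for ch in cons:
                if ch not in IUPAC:
                    raise DescriptorError(
                        f"{self.name}: invalid IUPAC character {ch!r} in segment {key}"
                    )
        missing = _REQUIRED_KEYS[self.motif_class] - set(self.segments)
        if missing:
            raise DescriptorError(
                f"{self.name}: missing required segment(s) {sorted(missing)}"
            )
        if self.motif_class in ("HL", "BL"):
            for k in range(1, _MAX_HL_PAIRS + 1):
                if (f"L{k}" in self.segments) != (f"R{k}" in self.segments):
                    raise DescriptorError(
                        f"{self.name}: correlated pair L{k}/R{k} must both be present"
                    )
        if self.motif_class not in ("J3", "J4"):
            if not any(self.segments.values()):
                raise DescriptorError(
                    f"{self.name}: all segments empty (only J3/J4 may coaxially stack)"
                )

    def linear_segments(self) -> tuple[tuple[str, str], ...]:
        """(name, consensus) pairs in 5'->3' order for HL/BL strands."""
        if self.motif_class not in ("HL", "BL"):
            raise ValueError("linear_segments applies to HL/BL only")
        ks = [k for k in range(1, _MAX_HL_PAIRS + 1) if f"L{k}" in self.segments]
        left = [(f"L{k}", self.segments[f"L{k}"]) for k in ks]
        right = [(f"R{k}", self.segments[f"R{k}"]) for k in reversed(ks)]
        return tuple(left + [("Loop", self.segments["Loop"])] + right)


@dataclass(frozen=True)
class MotifVariant:
    """One topological attachment of a motif.

    ``chains`` holds the consensus segments grouped by strand, in the
    rotated 5'->3' order in which the folding grammar will place them:
    one chain for HL/BL/BS, two for IL (left strand, right strand), and
    one single-segment chain per junction branch for J3/J4.
    """

    descriptor: MotifDescriptor
    topology_index: int
    chains: tuple[tuple[tuple[str, str], ...], ...]
    unique_id: str

    @property
    def motif_class(self) -> str:
        return self.descriptor.motif_class

    @property
    def name(self) -> str:
        return self.descriptor.name

    @property
    def attachment(self) -> str:
        """Grammar attachment point: HL, BL_left, BL_right, IL, J3, J4, BS."""
        cls = self.motif_class
        if cls == "BL":
            return "BL_left" if self.topology_index == 0 else "BL_right"
        return cls

    def signature(self) -> tuple:
        """Canonical key used for redundancy elimination."""
        cons = tuple(tuple(c for _, c in chain) for chain in self.chains)
        if self.motif_class == "BL":
            # left and right bulges generate different structures and are
            # never redundant with each other
            return (self.motif_class, self.attachment, cons)
        return (self.motif_class, cons)


def _variants_of(desc: MotifDescriptor) -> list[MotifVariant]:
    cls = desc.motif_class
    out: list[MotifVariant] = []
    if cls == "HL":
        out.append(MotifVariant(desc, 0, (desc.linear_segments(),), f"{desc.name}"))
    elif cls == "BL":
        lin = desc.linear_segments()
        out.append(MotifVariant(desc, 0, (lin,), f"{desc.name}.L"))
        out.append(MotifVariant(desc, 1, (lin,), f"{desc.name}.R"))
    elif cls == "IL":
        seg = desc.segments
        left = tuple((k, seg.get(k, "")) for k in ("Lo", "Loop1", "Li"))
        right = tuple((k, seg.get(k, "")) for k in ("Ri", "Loop2", "Ro"))
        out.append(MotifVariant(desc, 0, (left, right), f"{desc.name}.v1"))
        # rotated: the inner helix becomes the external attachment, which
        # swaps the roles of the two strands (5'->3' reading preserved)
        out.append(MotifVariant(desc, 1, (right, left), f"{desc.name}.v2"))
    elif cls in ("J3", "J4"):
        n = 3 if cls == "J3" else 4
        segs = [desc.segments[f"S{k + 1}"] for k in range(n)]
        names = [f"S{k + 1}" for k in range(n)]
        for r in range(n):
            chains = tuple(
                ((names[(r + k) % n], segs[(r + k) % n]),) for k in range(n)
            )
            out.append(MotifVariant(desc, r, chains, f"{desc.name}.v{r + 1}"))
    elif cls == "BS":
        out.append(MotifVariant(desc, 0, ((("S1", desc.segments["S1"]),),), desc.name))
    return out


def expand_variants(descriptors: list[MotifDescriptor]) -> list[MotifVariant]:
    """All topological variants of ``descriptors``, redundancy-eliminated.

    Deterministic and independent of descriptor order: variants are
    generated per descriptor in topology order and duplicates (same class
    and rotated consensus tuple within one descriptor's expansion or across
    descriptors) are merged, keeping the first.
    """
    seen: dict[tuple, MotifVariant] = {}
    total_before = 0
    for desc in descriptors:
        for var in _variants_of(desc):
            total_before += 1
            sig = var.signature()
            if sig not in seen:
                seen[sig] = var
    unique = list(seen.values())
    log.info(
        "motif library: %d descriptors -> %d variants, %d nonredundant",
        len(descriptors), total_before, len(unique),
    )
    return unique


def parse_descriptor_text(text: str, source: str = "<string>") -> list[MotifDescriptor]:
    descriptors: list[MotifDescriptor] = []
    names: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) < 2:
            raise DescriptorError(f"{source}:{lineno}: record needs CLASS NAME")
        cls, name, *pairs = fields
        if cls not in MOTIF_CLASSES:
            raise DescriptorError(f"{source}:{lineno}: unknown class token {cls!r}")
        if name in names:
            raise DescriptorError(f"{source}:{lineno}: duplicate motif name {name!r}")
        segments: dict[str, str] = {}
        for item in pairs:
            if "=" not in item:
                raise DescriptorError(
                    f"{source}:{lineno}: expected key=value, got {item!r}"
                )
            key, value = item.split("=", 1)
            if key in segments:
                raise DescriptorError(f"{source}:{lineno}: duplicate key {key!r}")
            segments[key] = value.upper().replace("T", "U")
        try:
            desc = MotifDescriptor(name=name, motif_class=cls, segments=segments)
        except DescriptorError as exc:
            raise DescriptorError(f"{source}:{lineno}: {exc}") from exc
        names.add(name)
        descriptors.append(desc)
    return descriptors


def parse_descriptor(path) -> list[MotifDescriptor]:
    """Parse an R3D descriptor file into motif descriptors."""
    with open(path) as fh:
        return parse_descriptor_text(fh.read(), source=str(path))


def builtin_descriptors() -> list[MotifDescriptor]:
    """The bundled motif library (see ``data/motifs.r3d``)."""
    text = resources.files("motiffold.data").joinpath("motifs.r3d").read_text()
    return parse_descriptor_text(text, source="motifs.r3d")
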