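"""Variable-length binary genome for joint feature/architecture/validation search.

A genome is a fixed maximum-length bit string laid out as::

    [ feature mask | validation bit | layer-count field | node fields ... ]

* ``n_feature_bits`` bits — one per candidate input feature (1 = selected);
* 1 bit — validation protocol (0 = hold-out, 1 = k-fold);
* ``layer_field_bits`` bits — number of hidden layers, decoded MSB-first
  as ``int(bits) + 1`` so zero hidden layers cannot occur;
* ``max_layers`` fields of ``node_field_bits`` bits each — nodes per hidden
  layer, decoded as ``int(bits) + 1``; only the first L fields are active,
  the rest are carried as neutral genetic material and never decoded.

The default layout (99 feature bits, 6 layer bits, 10 node bits) spans
architectures of 1-64 hidden layers with 1-1024 nodes each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EncodingSpec:
    n_feature_bits: int = 99
    layer_field_bits: int = 6
    node_field_bits: int = 10

    def __post_init__(self):
        for name in ("n_feature_bits", "layer_field_bits", "node_field_bits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def max_layers(self) -> int:
        return 2 ** self.layer_field_bits

    @property
    def max_nodes(self) -> int:
        return 2 ** self.node_field_bits

    @property
    def total_length(self) -> int:
        return (self.n_feature_bits + 1 + self.layer_field_bits
                + self.max_layers * self.node_field_bits)

    # field offsets
    @property
    def validation_bit(self) -> int:
        return self.n_feature_bits

    @property
    def layer_field_start(self) -> int:
        return self.n_feature_bits + 1

    @property
    def node_fields_start(self) -> int:
        return self.layer_field_start + self.layer_field_bits


@dataclass(frozen=True)
class Genome:
    """Fixed-length bit vector plus its layout spec.

    Bits beyond the active region (inactive node fields) are carried by
    variation operators but ignored at decode time.
    """

    bits: np.ndarray
    spec: EncodingSpec

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.ndim != 1 or bits.shape[0] != self.spec.total_length:
            raise ValueError(
                f"genome length {bits.shape[0]} != spec total {self.spec.total_length}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("genome bits must be 0/1")

    def to_string(self) -> str:
        return "".join("1" if b else "0" for b in self.bits)

    @classmethod
    def from_string(cls, s: str, spec: EncodingSpec) -> "Genome":
        return cls(np.frombuffer(s.encode(), dtype=np.uint8) - ord("0"), spec)

    def key(self, active_only: bool = True) -> bytes:
        """Hashable identity; by default only the decoded (active) region."""
        if not active_only:
            return self.bits.tobytes()
        p = decode(self)
        n = active_length(p, self.spec)
        return self.bits[:n].tobytes()


@dataclass(frozen=True)
class PhenotypeSpec:
    """Decoded genome: feature subset, validation protocol, architecture."""

    feature_mask: tuple
    validation: str  # "holdout" | "kfold"
    hidden_layers: tuple

    def __post_init__(self):
        object.__setattr__(self, "feature_mask", tuple(bool(b) for b in self.feature_mask))
        object.__setattr__(self, "hidden_layers", tuple(int(h) for h in self.hidden_layers))
        if len(self.hidden_layers) < 1:
            raise ValueError("at least one hidden layer required")
        if any(h < 1 for h in self.hidden_layers):
            raise ValueError("every hidden layer needs >= 1 node")
        if self.validation not in ("holdout", "kfold"):
            raise ValueError(f"unknown validation {self.validation!r}")

    @property
    def n_selected(self) -> int:
        return sum(self.feature_mask)

    @property
    def feasible(self) -> bool:
        return self.n_selected > 0

    def architecture_label(self) -> str:
        return ":".join(str(h) for h in self.hidden_layers)


def _bits_to_int(bits: np.ndarray) -> int:
    """MSB-first binary to decimal."""
    out = 0
    for b in bits:
        out = (out << 1) | int(b)
    return out


def _int_to_bits(value: int, width: int) -> np.ndarray:
    return np.array([(value >> (width - 1 - i)) & 1 for i in range(width)],
                    dtype=np.uint8)


def decode(g: Genome) -> PhenotypeSpec:
    """Decode a genome; pure function of the bits, total on any genome."""
    s = g.spec
    mask = g.bits[:s.n_feature_bits].astype(bool)
    validation = "kfold" if g.bits[s.validation_bit] else "holdout"
    L = _bits_to_int(g.bits[s.layer_field_start:s.layer_field_start + s.layer_field_bits]) + 1
    layers = []
    for i in range(L):
        start = s.node_fields_start + i * s.node_field_bits
        layers.append(_bits_to_int(g.bits[start:start + s.node_field_bits]) + 1)
    return PhenotypeSpec(feature_mask=tuple(mask), validation=validation,
                         hidden_layers=tuple(layers))


def encode(p: PhenotypeSpec, spec: EncodingSpec) -> Genome:
    """Inverse writer: phenotype -> genome with zeroed inactive tail."""
    if len(p.feature_mask) != spec.n_feature_bits:
        raise ValueError("feature_mask length mismatch")
    L = len(p.hidden_layers)
    if not 1 <= L <= spec.max_layers:
        raise ValueError(f"hidden layer count {L} outside [1, {spec.max_layers}]")
    if any(not 1 <= h <= spec.max_nodes for h in p.hidden_layers):
        raise ValueError("node count outside encodable range")
    bits = np.zeros(spec.total_length, dtype=np.uint8)
    bits[:spec.n_feature_bits] = np.asarray(p.feature_mask, dtype=np.uint8)
    bits[spec.validation_bit] = 1 if p.validation == "kfold" else 0
    bits[spec.layer_field_start:spec.layer_field_start + spec.layer_field_bits] = \
        _int_to_bits(L - 1, spec.layer_field_bits)
    for i, h in enumerate(p.hidden_layers):
        start = spec.node_fields_start + i * spec.node_field_bits
        bits[start:start + spec.node_field_bits] = _int_to_bits(h - 1, spec.node_field_bits)
    return Genome(bits, spec)


def active_length(p: PhenotypeSpec, spec: EncodingSpec) -> int:
    """Number of bits actually decoded for this phenotype."""
    return (spec.n_feature_bits + 1 + spec.layer_field_bits
            + len(p.hidden_layers) * spec.node_field_bits)


def random_genome(spec: EncodingSpec, rng: np.random.Generator) -> Genome:
    """Uniform random genome, repaired so the feature mask is never empty."""
    bits = rng.integers(0, 2, size=spec.total_length, dtype=np.uint8)
    if not bits[:spec.n_feature_bits].any():
        bits[rng.integers(0, spec.n_feature_bits)] = 1
    return Genome(bits, spec)
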