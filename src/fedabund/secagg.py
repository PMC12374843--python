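"""Exact additive secret sharing for federated aggregation.

Every cross-client numeric message in a study is a block of float64 values
whose element-wise *sum* is the only quantity the coordinator may learn.
Each client splits its block into ``n_parties`` additive shares over the
integers modulo a large prime: one "masked data" piece (the encoded block
minus all noise masks) plus ``n_parties - 1`` uniformly random noise pieces.
Pieces are exchanged so that no party holds more than one piece originating
from any client; each party sums what it received and forwards only that sum
to the coordinator, where the noise cancels exactly.

Encoding is binary fixed point with scale ``2**1075``.  Every finite float64
is an integer multiple of 2**-1074, so encoding is lossless and the decoded
secure sum equals the correctly rounded exact sum of the inputs (the same
value :func:`math.fsum` returns) -- aggregation adds *zero* numerical noise.
The modulus is the Mersenne prime 2**2203 - 1, comfortably larger than any
sum of encoded doubles for realistic party counts.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

#: Mersenne prime 2**2203 - 1; exceeds n * 2**2100 for any realistic n.
DEFAULT_MODULUS: int = 2**2203 - 1

#: Binary fixed-point scale: lossless for every finite float64.
DEFAULT_SCALE_BITS: int = 1075


@dataclass(frozen=True)
class FixedPointEncoding:
    """Lossless fixed-point embedding of float64 into Z_modulus."""

    scale_bits: int = DEFAULT_SCALE_BITS
    modulus: int = DEFAULT_MODULUS

    def encode(self, x: float) -> int:
        """Map a finite float to its exact scaled-integer residue."""
        if not math.isfinite(x):
            raise ValueError(f"cannot encode non-finite value {x!r}")
        # every double is an integer multiple of 2**-1074, so the shifted
        # 53-bit mantissa representation below is exact for any finite x
        m, e = math.frexp(float(x))
        mant = int(m * (1 << 53))
        shift = e - 53 + self.scale_bits
        i = mant << shift if shift >= 0 else mant >> -shift
        if not -self.modulus // 2 < i < self.modulus // 2:
            raise OverflowError(f"value {x!r} outside fixed-point range")
        return i % self.modulus

    def decode(self, i: int) -> float:
        i %= self.modulus
        if i > self.modulus // 2:
            i -= self.modulus
        try:
            # int/int true division is correctly rounded even for huge operands
            return i / (1 << self.scale_bits)
        except OverflowError:
            # residue outside the embedded float range (e.g. a raw share)
            return math.inf if i > 0 else -math.inf


@dataclass
class ShareSet:
    """Additive shares of one client's numeric block.

    ``pieces[0]`` is the masked-data piece, ``pieces[1:]`` are the noise
    masks.  Each piece is a flat list of residues; ``shape`` restores the
    original block layout.  The mod-q sum of all pieces decodes to the
    plaintext exactly.
    """

    shape: tuple[int, ...]
    pieces: list[list[int]]
    encoding: FixedPointEncoding = field(default_factory=FixedPointEncoding)

    @property
    def n_parties(self) -> int:
        return len(self.pieces)


def make_shares(
    block: np.ndarray,
    n_parties: int,
    encoding: FixedPointEncoding | None = None,
    rng: random.Random | None = None,
) -> ShareSet:
    """Split ``block`` into ``n_parties`` additive pieces over Z_modulus.

    Raises before emitting anything if any entry is non-finite or outside
    the fixed-point range, so a failed client never leaks partial shares.
    """
    if n_parties < 2:
        raise ValueError("secret sharing requires n_parties >= 2")
    enc = encoding or FixedPointEncoding()
    rng = rng or random.Random()
    arr = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("block contains non-finite entries; refusing to share")
    flat = arr.ravel()
    encoded = [enc.encode(v) for v in flat]
    q = enc.modulus
    masks = [[rng.randrange(q) for _ in flat] for _ in range(n_parties - 1)]
    data_piece = [
        (e - sum(m[j] for m in masks)) % q for j, e in enumerate(encoded)
    ]
    return ShareSet(shape=arr.shape, pieces=[data_piece] + masks, encoding=enc)


def reconstruct(shares: ShareSet) -> np.ndarray:
    """Recombine all pieces of a single ShareSet (testing helper)."""
    q = shares.encoding.modulus
    total = [sum(p[j] for p in shares.pieces) % q for j in range(len(shares.pieces[0]))]
    return np.array([shares.encoding.decode(t) for t in total]).reshape(shares.shape)


def secure_sum(
    local_blocks: list[np.ndarray],
    n_parties: int | None = None,
    encoding: FixedPointEncoding | None = None,
    rng: random.Random | None = None,
    transcript: list | None = None,
) -> np.ndarray:
    """Element-wise sum of per-client blocks via additive secret sharing.

    Simulates the full share-exchange topology in process: party ``p``
    receives exactly piece ``p`` from every client, sums the residues it
    holds, and only those ``n_parties`` partial sums reach the coordinator.
    The decoded result equals the exact real-number sum of the blocks,
    correctly rounded to float64.

    Parameters
    ----------
    transcript
        Optional list; if given, one entry per coordinator-visible message
        is appended (party partial sums only -- never client pieces).
    """
    if not local_blocks:
        raise ValueError("no blocks to aggregate")
    shapes = {np.asarray(b).shape for b in local_blocks}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across clients: {sorted(shapes)}")
    (shape,) = shapes
    n = n_parties or max(len(local_blocks), 2)
    enc = encoding or FixedPointEncoding()
    rng = rng or random.Random()
    q = enc.modulus

    sharesets = [make_shares(b, n, enc, rng) for b in local_blocks]
    size = len(sharesets[0].pieces[0])
    # party p holds piece p of every client; no party sees two pieces of one client
    party_sums = []
    for p in range(n):
        acc = [0] * size
        for ss in sharesets:
            piece = ss.pieces[p]
            for j in range(size):
                acc[j] = (acc[j] + piece[j]) % q
        party_sums.append(acc)
        if transcript is not None:
            transcript.append(("party_partial_sum", p, shape))
    total = [0] * size
    for acc in party_sums:
        for j in range(size):
            total[j] = (total[j] + acc[j]) % q
    return np.array([enc.decode(t) for t in total]).reshape(shape)
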