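"""Adaptive range coding.

A byte-wise renormalizing range coder (64-bit low with carry propagation,
32-bit range) driving adaptive per-context frequency models.  Every codec
in the package funnels its symbols through this module; the bitstream
layout is documented in docs/bitstream.md.

Residual integers (coordinate deltas, column deltas) are binarized as a
*bucket* symbol — sign plus magnitude class, Elias-gamma style — followed
by raw offset bits, so the entropy-coded cost of a residual d tracks
``log2(1+|d|)`` up to a constant.
"""

from __future__ import annotations

from .errors import TruncatedStream

_TOP = 1 << 24
_MASK32 = 0xFFFFFFFF

#: adaptive model tuning: fast adaptation for short per-file streams
MODEL_INCREMENT = 32
RESCALE_THRESHOLD = 1 << 16


class FrequencyModel:
    """Adaptive order-0 frequency table over a fixed alphabet.

    Counts start at 1, grow by :data:`MODEL_INCREMENT` per coded symbol and
    are halved (rounding up, so counts stay >= 1) once the total reaches
    :data:`RESCALE_THRESHOLD`.
    """

    __slots__ = ("counts", "total")

    def __init__(self, alphabet_size: int) -> None:
        if alphabet_size < 1:
            raise ValueError("alphabet_size must be >= 1")
        self.counts = [1] * alphabet_size
        self.total = alphabet_size

    def freq(self, symbol: int) -> tuple[int, int, int]:
        counts = self.counts
        if not 0 <= symbol < len(counts):
            raise ValueError(f"symbol {symbol} outside alphabet [0, {len(counts)})")
        cum = 0
        for s in range(symbol):
            cum += counts[s]
        return cum, counts[symbol], self.total

    def find(self, target: int) -> tuple[int, int, int]:
        """Symbol whose cumulative interval contains *target*."""
        cum = 0
        for s, c in enumerate(self.counts):
            if cum + c > target:
                return s, cum, c
            cum += c
        raise TruncatedStream("decoded frequency outside model range")

    def update(self, symbol: int) -> None:
        self.counts[symbol] += MODEL_INCREMENT
        self.total += MODEL_INCREMENT
        if self.total >= RESCALE_THRESHOLD:
            total = 0
            counts = self.counts
            for s in range(len(counts)):
                counts[s] = (counts[s] + 1) >> 1
                total += counts[s]
            self.total = total


class ContextedModelBank:
    """One :class:`FrequencyModel` per context id, allocated lazily."""

    def __init__(self, context_count: int, alphabet_size: int) -> None:
        self.context_count = context_count
        self.alphabet_size = alphabet_size
        self._models: dict[int, FrequencyModel] = {}

    def model(self, context_id: int) -> FrequencyModel:
        if not 0 <= context_id < self.context_count:
            raise ValueError(f"context id {context_id} outside "
                             f"[0, {self.context_count})")
        m = self._models.get(context_id)
        if m is None:
            m = self._models[context_id] = FrequencyModel(self.alphabet_size)
        return m


class RangeEncoder:
    """Carry-propagating byte-wise range encoder."""

    def __init__(self) -> None:
        self.low = 0
        self.range = _MASK32
        self.cache = 0
        self.cache_size = 1
        self.out = bytearray()

    def _shift_low(self, force: bool = False) -> None:
        if force or self.low < 0xFF000000 or self.low > _MASK32:
            carry = self.low >> 32
            temp = self.cache
            while self.cache_size:
                self.out.append((temp + carry) & 0xFF)
                temp = 0xFF
                self.cache_size -= 1
            self.cache = (self.low >> 24) & 0xFF
        self.cache_size += 1
        self.low = (self.low & 0xFFFFFF) << 8

    def encode(self, cum: int, freq: int, total: int) -> None:
        r = self.range // total
        self.low += cum * r
        self.range = r * freq
        while self.range < _TOP:
            self._shift_low()
            self.range <<= 8

    def encode_symbol(self, model: FrequencyModel, symbol: int) -> None:
        cum, freq, total = model.freq(symbol)
        self.encode(cum, freq, total)
        model.update(symbol)

    def encode_bits(self, value: int, nbits: int) -> None:
        """Raw bits at a fixed cost of one bit each (no adaptation)."""
        for i in range(nbits - 1, -1, -1):
            self.encode((value >> i) & 1, 1, 2)

    def finish(self) -> bytes:
        for _ in range(5):
            self._shift_low(force=True)
        return bytes(self.out)


class RangeDecoder:
    def __init__(self, stream: bytes) -> None:
        self._data = stream
        self._pos = 0
        self.range = _MASK32
        self.code = 0
        for _ in range(5):
            self.code = ((self.code << 8) | self._byte()) & 0xFFFFFFFFFF
        self.code &= _MASK32

    def _byte(self) -> int:
        if self._pos >= len(self._data):
            raise TruncatedStream("range-coded stream truncated")
        b = self._data[self._pos]
        self._pos += 1
        return b

    def _decode_target(self, total: int) -> int:
        self._r = self.range // total
        t = self.code // self._r
        return total - 1 if t >= total else t

    def _decode_update(self, cum: int, freq: int) -> None:
        self.code -= cum * self._r
        self.range = self._r * freq
        while self.range < _TOP:
            self.code = ((self.code << 8) | self._byte()) & 0xFFFFFFFFFF
            self.code &= _MASK32
            self.range <<= 8

    def decode_symbol(self, model: FrequencyModel) -> int:
        target = self._decode_target(model.total)
        symbol, cum, freq = model.find(target)
        self._decode_update(cum, freq)
        model.update(symbol)
        return symbol

    def decode_bits(self, nbits: int) -> int:
        v = 0
        for _ in range(nbits):
            bit = self._decode_target(2)
            self._decode_update(bit, 1)
            v = (v << 1) | bit
        return v


def rc_encode(symbols, bank: ContextedModelBank) -> bytes:
    """Encode ``(context_id, symbol)`` pairs against *bank*."""
    enc = RangeEncoder()
    for ctx, sym in symbols:
        enc.encode_symbol(bank.model(ctx), sym)
    return enc.finish()


def rc_decode(stream: bytes, bank: ContextedModelBank, plan) -> list[int]:
    """Decode one symbol per context id in *plan* (an iterable; in real
    codecs the next context is derived from already-decoded data)."""
    dec = RangeDecoder(stream)
    return [dec.decode_symbol(bank.model(ctx)) for ctx in plan]


# --- residual binarization ------------------------------------------------

#: bucket 0 = zero; 1..31 positive classes; 32..62 negative classes
RESIDUAL_ALPHABET = 63
_MAX_CLASS = 30


def encode_residual(value: int) -> tuple[int, int, int]:
    """Map a signed integer to ``(bucket, n_extra_bits, extra_bits)``.

    Class c covers magnitudes [2^c, 2^(c+1)); the offset within the class
    is sent as c raw bits, so the total cost is about ``log2(1+|value|)``
    plus the entropy-coded bucket.
    """
    if value == 0:
        return 0, 0, 0
    mag = abs(value)
    c = mag.bit_length() - 1
    if c > _MAX_CLASS:
        raise ValueError("residual magnitude exceeds 2^31")
    base = 1 if value > 0 else 1 + _MAX_CLASS + 1
    return base + c, c, mag - (1 << c)


def decode_residual(bucket: int, extra: int) -> int:
    if bucket == 0:
        return 0
    if bucket <= _MAX_CLASS + 1:
        c = bucket - 1
        return (1 << c) + extra
    c = bucket - (_MAX_CLASS + 2)
    return -((1 << c) + extra)


def residual_class_bits(bucket: int) -> int:
    """Number of raw offset bits that follow a given bucket symbol."""
    if bucket == 0:
        return 0
    return bucket - 1 if bucket <= _MAX_CLASS + 1 else bucket - (_MAX_CLASS + 2)


def put_residual(enc: RangeEncoder, model: FrequencyModel, value: int) -> None:
    bucket, nbits, extra = encode_residual(value)
    enc.encode_symbol(model, bucket)
    if nbits:
        enc.encode_bits(extra, nbits)


def get_residual(dec: RangeDecoder, model: FrequencyModel) -> int:
    bucket = dec.decode_symbol(model)
    nbits = residual_class_bits(bucket)
    extra = dec.decode_bits(nbits) if nbits else 0
    return decode_residual(bucket, extra)
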