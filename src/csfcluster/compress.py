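"""Compression back-ends used to approximate Kolmogorov complexity.

The prefix complexity K(x) — the length of the shortest program printing x —
is uncomputable.  Following the standard practice of compression-based
similarity, a real lossless compressor Z stands in for K from above: Z(x) is
the length in bytes of the compressed form of x.  Everything downstream
(optimality deficiencies, the cluster structure function, NCD) reduces to
calls into this module.

Two serialization dialects exist for multisets:

* ``prefix_free`` — the self-delimiting bit encoding 1^|x| 0 x per element,
  used only for bit-exact tests of the encoding length identity
  |s(A)| = sum(2|x_i| + 1).  Its unary length prefix makes it useless as a
  practical compressor input.
* ``concat`` — plain concatenation of the elements' byte streams (or a
  vertical stack for image arrays), which is what every compressor call in
  the practical pipeline uses.
"""
from __future__ import annotations

import bz2
import hashlib
import io
import lzma
import zlib
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np

from .core import ConfigurationError, DataError

__all__ = [
    "CompressorSpec",
    "SerializedMultiset",
    "Compressor",
    "serialize_multiset",
    "deserialize_multiset",
    "compressed_size",
    "ncd",
    "available_backends",
]


@dataclass(frozen=True)
class CompressorSpec:
    """Identifies a registered compression backend plus its options.

    Options are stored as a sorted tuple of (key, value) pairs so specs are
    hashable and usable as cache keys; use :meth:`make` to build one from
    keyword arguments.
    """

    name: str = "deflate"
    options: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(cls, name: str = "deflate", **options: Any) -> "CompressorSpec":
        return cls(name=name, options=tuple(sorted(options.items())))

    def opts(self) -> dict[str, Any]:
        return dict(self.options)


@dataclass
class SerializedMultiset:
    """A serialized ordered multiset: the payload plus the element count."""

    payload: Any  # str of '0'/'1' for prefix_free, bytes for concat
    element_count: int


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[[bytes, dict], int]] = {}


def _register(name: str):
    def deco(fn):
        _BACKENDS[name] = fn
        return fn
    return deco


def available_backends() -> list[str]:
    return sorted(_BACKENDS)


@_register("deflate")
def _deflate_size(data: bytes, options: dict) -> int:
    return len(zlib.compress(data, options.get("level", 9)))


@_register("bzip2")
def _bzip2_size(data: bytes, options: dict) -> int:
    return len(bz2.compress(data, options.get("level", 9)))


@_register("lzma")
def _lzma_size(data: bytes, options: dict) -> int:
    return len(lzma.compress(data, preset=options.get("preset", 6)))


def _png_bytes(arr: np.ndarray, options: dict) -> bytes:
    from PIL import Image

    if arr.ndim != 2:
        raise DataError("png backend expects 2-D grayscale arrays")
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.floating):
            arr = np.clip(arr, 0.0, 1.0)
            arr = (arr * 255.0 + 0.5).astype(np.uint8)
        else:
            arr = arr.astype(np.uint8)
    buf = io.BytesIO()
    Image.fromarray(arr, mode="L").save(
        buf, format="PNG", optimize=bool(options.get("optimize", False)),
        compress_level=options.get("level", 6))
    return buf.getvalue()


@_register("png")
def _png_size(data: bytes, options: dict) -> int:  # pragma: no cover
    # bytes fed to the png backend are re-wrapped as a 1-row image; image
    # objects take the dedicated array path in Compressor instead.
    arr = np.frombuffer(data, dtype=np.uint8).reshape(1, -1)
    return len(_png_bytes(arr, options))


def to_bytes(obj: Any) -> bytes:
    """Canonical byte stream of an object for byte-oriented compressors."""
    if isinstance(obj, (bytes, bytearray, memoryview)):
        return bytes(obj)
    if isinstance(obj, str):
        return obj.encode("utf-8")
    if isinstance(obj, np.ndarray):
        return np.ascontiguousarray(obj).tobytes()
    raise DataError(f"cannot serialize object of type {type(obj).__name__}")


class Compressor:
    """A backend bound to its options, with a content-addressed size cache."""

    def __init__(self, spec: CompressorSpec | None = None):
        self.spec = spec or CompressorSpec()
        if self.spec.name not in _BACKENDS:
            raise ConfigurationError(
                f"unknown compressor backend {self.spec.name!r}; "
                f"available: {available_backends()}")
        self._options = self.spec.opts()
        self._cache: dict[bytes, int] = {}

    # -- sizes --------------------------------------------------------------

    def size(self, obj: Any) -> int:
        """Compressed length Z(obj) in bytes (deterministic, cached)."""
        if self.spec.name == "png" and isinstance(obj, np.ndarray):
            raw = to_bytes(obj) + repr(obj.shape).encode()
            key = hashlib.sha1(raw).digest()
            if key not in self._cache:
                self._cache[key] = len(_png_bytes(obj, self._options))
            return self._cache[key]
        data = to_bytes(obj)
        key = hashlib.sha1(data).digest()
        if key not in self._cache:
            self._cache[key] = _BACKENDS[self.spec.name](data, self._options)
        return self._cache[key]

    def concat(self, objs: Sequence[Any]) -> Any:
        """Concatenate objects the way this backend compresses them."""
        if self.spec.name == "png":
            arrs = [o for o in objs]
            if not all(isinstance(a, np.ndarray) for a in arrs):
                raise DataError("png backend concatenates image arrays only")
            return np.concatenate(arrs, axis=0)
        return b"".join(to_bytes(o) for o in objs)

    def size_of_concat(self, objs: Sequence[Any]) -> int:
        if len(objs) == 0:
            return self.size(b"")
        return self.size(self.concat(objs))

    # -- NCD ----------------------------------------------------------------

    def ncd(self, x: Any, y: Any) -> float:
        """Normalized compression distance, symmetrized over both orders.

        NCD(x, y) = (Z(xy) - min(Z(x), Z(y))) / max(Z(x), Z(y)); real
        compressors are order-sensitive, so the two concatenation orders are
        averaged, which makes the result exactly symmetric.
        """
        zx, zy = self.size(x), self.size(y)
        denom = max(zx, zy)
        if denom == 0:
            raise DataError("NCD undefined: both inputs compress to size 0")
        zxy = self.size_of_concat([x, y])
        zyx = self.size_of_concat([y, x])
        lo = min(zx, zy)
        return 0.5 * ((zxy - lo) / denom + (zyx - lo) / denom)


# module-level convenience wrappers share one Compressor per spec so the
# size cache survives across calls
_INSTANCES: dict[CompressorSpec, Compressor] = {}


def get_compressor(spec: CompressorSpec | None = None) -> Compressor:
    spec = spec or CompressorSpec()
    if spec not in _INSTANCES:
        _INSTANCES[spec] = Compressor(spec)
    return _INSTANCES[spec]


def compressed_size(x: Any, spec: CompressorSpec | None = None) -> int:
    return get_compressor(spec).size(x)


def ncd(x: Any, y: Any, spec: CompressorSpec | None = None) -> float:
    return get_compressor(spec).ncd(x, y)


# ---------------------------------------------------------------------------
# multiset serialization
# ---------------------------------------------------------------------------

def serialize_multiset(A: Sequence[Any], dialect: str = "concat",
                       spec: CompressorSpec | None = None) -> SerializedMultiset:
    """Serialize an ordered multiset.

    ``prefix_free`` expects bit strings (str over '0'/'1') and emits the
    self-delimiting code 1^|x| 0 x per element, so the payload length in bits
    is exactly sum(2|x_i| + 1).  ``concat`` emits the raw concatenation used
    as compressor input.
    """
    if dialect == "prefix_free":
        parts = []
        for x in A:
            if not isinstance(x, str) or set(x) - {"0", "1"}:
                raise DataError("prefix_free dialect requires bit strings")
            parts.append("1" * len(x) + "0" + x)
        return SerializedMultiset("".join(parts), len(A))
    if dialect == "concat":
        comp = get_compressor(spec)
        if len(A) == 0:
            return SerializedMultiset(b"", 0)
        return SerializedMultiset(comp.concat(list(A)), len(A))
    raise ConfigurationError(f"unknown dialect {dialect!r}")


def deserialize_multiset(s: SerializedMultiset | str) -> list[str]:
    """Invert the prefix_free dialect back to the ordered multiset."""
    payload = s.payload if isinstance(s, SerializedMultiset) else s
    out: list[str] = []
    i = 0
    n = len(payload)
    while i < n:
        j = i
        while j < n and payload[j] == "1":
            j += 1
        if j >= n:
            raise DataError("truncated prefix_free payload: missing 0 marker")
        length = j - i
        start = j + 1
        if start + length > n:
            raise DataError("truncated prefix_free payload: short element")
        out.append(payload[start:start + length])
        i = start + length
    return out
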