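"""Shared containers and error types."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np


class CSFError(Exception):
    """Base class for package errors."""


class ConfigurationError(CSFError):
    """Bad configuration: unknown backend, invalid parameter, unknown key."""


class DataError(CSFError):
    """Structurally invalid input data (shape mismatch, empty part, ...)."""


@dataclass
class ObjectSet:
    """Ordered multiset of data objects with stable string ids.

    Objects may be byte strings, text strings (compressed as UTF-8) or 2-D
    numpy arrays (grayscale images).  Duplicates are allowed; order is
    preserved and meaningful only for reproducibility, never for results.
    """

    objects: list[Any]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.objects = list(self.objects)
        if not self.ids:
            self.ids = [f"obj{i:04d}" for i in range(len(self.objects))]
        if len(self.ids) != len(self.objects):
            raise DataError("ids and objects must have equal length")

    def __len__(self) -> int:
        return len(self.objects)

    def __iter__(self) -> Iterator[Any]:
        return iter(self.objects)

    def __getitem__(self, i: int) -> Any:
        return self.objects[i]

    def subset(self, indices: Sequence[int]) -> "ObjectSet":
        return ObjectSet([self.objects[i] for i in indices],
                         [self.ids[i] for i in indices])


def as_object_list(S: "ObjectSet | Sequence[Any]") -> list[Any]:
    """Accept either an ObjectSet or a plain sequence of objects."""
    if isinstance(S, ObjectSet):
        return list(S.objects)
    return list(S)


def object_equal(a: Any, b: Any) -> bool:
    """Equality that also works for array-valued objects."""
    if a is b:
        return True
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return isinstance(a, np.ndarray) and isinstance(b, np.ndarray) \
            and a.shape == b.shape and bool(np.array_equal(a, b))
    try:
        return bool(a == b)
    except Exception:
        return False
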