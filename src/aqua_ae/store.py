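"""Quantized Base64 latent storage under a date/hour key layout.

A CNN latent of shape (32, 32, 64) holds 65,536 values; stored at one byte
per element it occupies exactly 64 KB, and its Base64 text form is
4·ceil(n/3) = 87,384 characters (~85.3 KB, bounded by 86 KB). Quantization
is linear min-max to uint8 with the (qmin, qmax) range kept alongside, so
dequantization recovers each value to within half a quantization step,
0.5/255 of the range.

Records are JSON documents filed as ``{date}/{hour}/{source}-{sequence}``
under a filesystem root — the put/get/list-by-prefix contract any document
database would satisfy, without a server dependency.
"""

from __future__ import annotations

import base64
import binascii
import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

__all__ = [
    "LatentRecord",
    "FileStore",
    "StoreError",
    "quantize",
    "dequantize",
    "to_base64",
    "from_base64",
]


class StoreError(RuntimeError):
    """Missing key or corrupted record."""


def quantize(latent: np.ndarray) -> tuple[bytes, float, float]:
    """Linear min-max quantization to one uint8 byte per element.

    Maps [qmin, qmax] onto {0..255} with round-half-up; qmin/qmax are the
    observed extremes. A constant tensor yields an all-zero payload with
    qmin == qmax.
    """
    latent = np.asarray(latent, dtype=np.float64)
    if not np.all(np.isfinite(latent)):
        raise ValueError("quantize: latent contains non-finite values")
    qmin = float(latent.min())
    qmax = float(latent.max())
    if qmax == qmin:
        return bytes(latent.size), qmin, qmax
    scaled = (latent - qmin) / (qmax - qmin) * 255.0
    q = np.floor(scaled + 0.5).astype(np.uint8)  # round half up
    return q.tobytes(), qmin, qmax


def dequantize(
    payload: bytes, shape: tuple[int, ...], qmin: float, qmax: float
) -> np.ndarray:
    """Inverse of :func:`quantize` up to half a quantization step."""
    expected = int(np.prod(shape))
    if len(payload) != expected:
        raise ValueError(f"payload has {len(payload)} bytes, shape implies {expected}")
    q = np.frombuffer(payload, dtype=np.uint8).astype(np.float64)
    if qmax == qmin:
        values = np.full(expected, qmin)
    else:
        values = qmin + q / 255.0 * (qmax - qmin)
    return values.reshape(shape)


def to_base64(payload: bytes) -> str:
    """Standard padded Base64; length is exactly 4·ceil(n/3)."""
    return base64.b64encode(payload).decode("ascii")


def from_base64(text: str) -> bytes:
    try:
        return base64.b64decode(text.encode("ascii"), validate=True)
    except (binascii.Error, UnicodeEncodeError) as exc:
        raise ValueError(f"malformed Base64 text: {exc}") from exc


def base64_length(n_bytes: int) -> int:
    """Length in characters of the padded Base64 encoding of n bytes."""
    return 4 * math.ceil(n_bytes / 3)


@dataclass(frozen=True)
class LatentRecord:
    """One stored latent: quantized payload plus capture metadata.

    ``capture_timestamp`` is ISO-8601; ``bbox`` is the optional source crop
    box [x0, y0, x1, y1]; ``model_id`` names the producing autoencoder.
    """

    latent_shape: tuple[int, ...]
    payload: bytes
    qmin: float
    qmax: float
    capture_timestamp: str
    source_id: str
    model_id: str
    bbox: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        expected = int(np.prod(self.latent_shape))
        if len(self.payload) != expected:
            raise ValueError(
                f"payload length {len(self.payload)} != product(shape) {expected}"
            )
        object.__setattr__(self, "latent_shape", tuple(int(d) for d in self.latent_shape))
        if self.bbox is not None:
            object.__setattr__(self, "bbox", tuple(int(v) for v in self.bbox))
        # validate the timestamp eagerly so keys are always derivable
        datetime.fromisoformat(self.capture_timestamp)

    @property
    def encoded(self) -> str:
        return to_base64(self.payload)

    @classmethod
    def from_latent(
        cls,
        latent: np.ndarray,
        capture_timestamp: str,
        source_id: str,
        model_id: str,
        bbox: tuple[int, int, int, int] | None = None,
    ) -> "LatentRecord":
        payload, qmin, qmax = quantize(latent)
        return cls(
            latent_shape=tuple(np.asarray(latent).shape),
            payload=payload,
            qmin=qmin,
            qmax=qmax,
            capture_timestamp=capture_timestamp,
            source_id=source_id,
            model_id=model_id,
            bbox=bbox,
        )

    def to_latent(self) -> np.ndarray:
        return dequantize(self.payload, self.latent_shape, self.qmin, self.qmax)

    def to_json(self) -> str:
        return json.dumps(
            {
                "shape": list(self.latent_shape),
                "qmin": self.qmin,
                "qmax": self.qmax,
                "b64": self.encoded,
                "meta": {
                    "ts": self.capture_timestamp,
                    "source": self.source_id,
                    "bbox": list(self.bbox) if self.bbox is not None else None,
                    "model": self.model_id,
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LatentRecord":
        try:
            doc = json.loads(text)
            return cls(
                latent_shape=tuple(doc["shape"]),
                payload=from_base64(doc["b64"]),
                qmin=float(doc["qmin"]),
                qmax=float(doc["qmax"]),
                capture_timestamp=doc["meta"]["ts"],
                source_id=doc["meta"]["source"],
                model_id=doc["meta"]["model"],
                bbox=tuple(doc["meta"]["bbox"]) if doc["meta"]["bbox"] is not None else None,
            )
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise StoreError(f"corrupted latent record: {exc}") from exc


_SAFE = re.compile(r"[^A-Za-z0-9_.-]")


@dataclass
class FileStore:
    """Filesystem-backed key-value store of latent records.

    Keys are ``{YYYY-MM-DD}/{HH}/{source}-{sequence}``, derived from each
    record's capture timestamp; documents are one JSON file per record.
    Listing by key prefix returns keys in lexicographic (hence timestamp)
    order.
    """

    root: Path
    _counters: dict[str, int] = field(default_factory=dict)

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._counters = {}

    def _path(self, key: str) -> Path:
        return self.root / (key + ".json")

    def put(self, record: LatentRecord) -> str:
        ts = datetime.fromisoformat(record.capture_timestamp)
        source = _SAFE.sub("_", record.source_id) or "src"
        hour_dir = f"{ts.date().isoformat()}/{ts.hour:02d}"
        base = f"{hour_dir}/{source}"
        seq = self._counters.get(base, 0)
        while self._path(f"{base}-{seq:06d}").exists():
            seq += 1
        key = f"{base}-{seq:06d}"
        self._counters[base] = seq + 1
        path = self._path(key)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(record.to_json())
        return key

    def get(self, key: str) -> LatentRecord:
        path = self._path(key)
        if not path.exists():
            raise StoreError(f"no record under key {key!r}")
        return LatentRecord.from_json(path.read_text())

    def list_keys(self, prefix: str = "") -> list[str]:
        keys = [
            str(p.relative_to(self.root))[: -len(".json")]
            for p in self.root.rglob("*.json")
        ]
        return sorted(k for k in keys if k.startswith(prefix))
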