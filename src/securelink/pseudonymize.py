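"""Keyed one-way fingerprinting of identifier fields.

An unsalted hash of a low-entropy identifier (a name, a national number) is
vulnerable to dictionary attack: an adversary who knows the hash function
precomputes the fingerprints of all plausible values. Appending a secret
hashing key (a *salt*) to the value before hashing defeats this, while
keeping the mapping deterministic so that equal values still collide —
which is exactly what linkage needs.

*Double hashing* applies a second keyed hash on top of the first, with a
different key held by a different party: the party comparing the doubly
hashed identifiers holds neither the cleartext nor the first key, so it can
neither read nor dictionary-attack them, yet equality is preserved.

The hash algorithm is fixed to SHA-256 (the algorithm recommended by ANSSI,
the French national information-security agency); weaker digests are
deliberately not offered.
"""

from __future__ import annotations

import hashlib
import hmac
import os
import re
from dataclasses import dataclass, field

__all__ = [
    "HashKey",
    "Fingerprint",
    "KeyConfigError",
    "hash_value",
    "double_hash",
    "block_hash_similarity",
    "derive_record_key",
    "load_key_file",
]

_HEX64 = re.compile(r"^[0-9a-f]{64}$")


class KeyConfigError(ValueError):
    """Invalid hashing-key configuration (empty secret, reused key, ...)."""


@dataclass(frozen=True)
class HashKey:
    """A secret hashing key (salt).

    Only ``key_id`` may ever appear in logs or outputs; the secret itself is
    excluded from ``repr`` and never serialized by this package.
    """

    key_id: str
    secret: bytes = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.secret, (bytes, bytearray)) or len(self.secret) < 1:
            raise KeyConfigError(f"key {self.key_id!r}: secret must be at least 1 byte")

    @classmethod
    def from_text(cls, key_id: str, secret: str) -> "HashKey":
        return cls(key_id, secret.encode("utf-8"))


@dataclass(frozen=True)
class Fingerprint:
    """A SHA-256 fingerprint: exactly 64 lowercase hex characters."""

    hex: str

    def __post_init__(self) -> None:
        if not _HEX64.match(self.hex):
            raise ValueError("fingerprint must be 64 lowercase hex characters")

    def __str__(self) -> str:
        return self.hex

    @property
    def bits(self) -> int:
        return int(self.hex, 16)


def hash_value(value: str, key: HashKey | None = None, *, salt_position: str = "suffix") -> Fingerprint:
    """SHA-256 fingerprint of ``value``, salted with ``key`` if given.

    The secret is concatenated to the UTF-8 bytes of ``value`` — by default
    as a suffix (``value + secret``), the variant that reproduces the
    published example ``SHA256("DupontXZ!#45")``; ``salt_position="prefix"``
    puts it in front instead.

    >>> hash_value("Dupont").hex[:8]
    '3bde3a59'
    """
    data = value.encode("utf-8")
    if key is not None:
        if salt_position == "suffix":
            data = data + key.secret
        elif salt_position == "prefix":
            data = key.secret + data
        else:
            raise KeyConfigError(f"unknown salt position {salt_position!r}")
    return Fingerprint(hashlib.sha256(data).hexdigest())


def double_hash(value: str, k1: HashKey, k2: HashKey, *, strict: bool = True,
                salt_position: str = "suffix") -> Fingerprint:
    """Hash ``value`` with ``k1``, then hash the hex fingerprint with ``k2``.

    Equal inputs under equal keys give equal outputs, which is what makes a
    join on doubly hashed identifiers possible. Using the same secret for
    both keys defeats the two-party compartmentalization the scheme exists
    for; in strict mode (default) that raises :class:`KeyConfigError`.
    """
    if k1.secret == k2.secret:
        if strict:
            raise KeyConfigError("k1 and k2 share the same secret; double hashing "
                                 "requires two independent keys")
    first = hash_value(value, k1, salt_position=salt_position)
    return hash_value(first.hex, k2, salt_position=salt_position)


def block_hash_similarity(a: str, b: str, n: int, key: HashKey) -> float:
    """Similarity of two strings computed on separately hashed blocks.

    Equality of full-string fingerprints is all-or-nothing; splitting each
    (already normalized) string into consecutive ``n``-character blocks and
    hashing each block separately allows a graded comparison without ever
    exposing cleartext: the score is the fraction of block positions where
    the two block fingerprints are equal, over the block count of the longer
    string (so a length mismatch is penalized).

    >>> k = HashKey.from_text("demo", "s")
    >>> block_hash_similarity("dupont", "dupond", 2, k)
    0.6666666666666666
    """
    if n < 1:
        raise KeyConfigError("block size must be >= 1")
    blocks_a = [hash_value(a[i:i + n], key) for i in range(0, len(a), n)]
    blocks_b = [hash_value(b[i:i + n], key) for i in range(0, len(b), n)]
    longest = max(len(blocks_a), len(blocks_b))
    if longest == 0:
        return 1.0
    equal = sum(1 for fa, fb in zip(blocks_a, blocks_b) if fa == fb)
    return equal / longest


def derive_record_key(master: HashKey, record_field: str) -> HashKey:
    """Derive a per-record salt from a master key and a record-specific field.

    HMAC-SHA256 keyed by the master secret. A different salt per record makes
    dictionary attacks per-record expensive, but it also destroys
    linkability across files, so this derivation must never be applied to
    the fields used for linkage — only to fields pseudonymized for storage.
    """
    derived = hmac.new(master.secret, record_field.encode("utf-8"), hashlib.sha256).digest()
    return HashKey(key_id=f"{master.key_id}/record", secret=derived)


def load_key_file(path: str, key_id: str | None = None) -> HashKey:
    """Load a hashing key from a raw-bytes file.

    Warns (via the return path's caller logging, never printing the secret)
    only through exceptions; refuses group/world-readable files on POSIX so
    that sloppy key handling fails fast.
    """
    mode = os.stat(path).st_mode
    if mode & 0o077:
        raise KeyConfigError(f"key file {path} is readable by group/others; "
                             f"chmod 600 it first")
    with open(path, "rb") as fh:
        secret = fh.read()
    return HashKey(key_id or os.path.basename(path), secret)
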