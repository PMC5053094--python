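"""Asymmetric encryption primitives for the linkage protocol.

The protocol needs exactly three public-key operations: randomized
confidentiality encryption of a short plaintext (a fingerprint plus a
random chain — it fits a single RSA block at standard key sizes, so no
hybrid session-key layer is needed), the matching decryption, and
signatures to authenticate key-distribution messages.

This module implements textbook RSA with OAEP padding (SHA-256 / MGF1,
RFC 8017 construction) and full-domain-hash signatures directly on Python
integers. This is a *simulation-grade* implementation: the arithmetic and
padding are the standard ones, but no effort is made to be constant-time
or side-channel resistant, which is irrelevant for a single-process
protocol simulation and would be negligent in a networked deployment.

Key generation is deterministic given an RNG, so a seeded study reproduces
byte-identical keys; pass ``random.SystemRandom()`` for real entropy.
"""

from __future__ import annotations

import base64
import hashlib
import json
import math
import random
from dataclasses import dataclass

import sympy

__all__ = [
    "RSAPublicKey",
    "RSAPrivateKey",
    "CryptoError",
    "generate_keypair",
    "encrypt",
    "decrypt",
    "sign",
    "verify",
    "public_key_to_pem",
    "private_key_to_pem",
    "key_from_pem",
]

_HASH = hashlib.sha256
_HLEN = 32


class CryptoError(ValueError):
    """Encryption, decryption or signature failure."""


@dataclass(frozen=True)
class RSAPublicKey:
    n: int
    e: int

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8

    @property
    def max_message_bytes(self) -> int:
        """Longest plaintext OAEP can carry in one block."""
        return self.size_bytes - 2 * _HLEN - 2


@dataclass(frozen=True, repr=False)
class RSAPrivateKey:
    n: int
    e: int
    d: int
    p: int
    q: int

    def __repr__(self) -> str:  # never leak private material through repr
        return f"RSAPrivateKey(n_bits={self.n.bit_length()})"

    @property
    def public(self) -> RSAPublicKey:
        return RSAPublicKey(self.n, self.e)

    @property
    def size_bytes(self) -> int:
        return (self.n.bit_length() + 7) // 8


def _random_prime(bits: int, rng: random.Random) -> int:
    while True:
        cand = rng.getrandbits(bits) | (1 << (bits - 1)) | (1 << (bits - 2)) | 1
        if sympy.isprime(cand):
            return cand


def generate_keypair(bits: int = 2048, rng: random.Random | None = None) -> RSAPrivateKey:
    """Generate an RSA key pair; ``bits`` is the modulus size.

    2048-bit keys carry OAEP plaintexts up to 190 bytes, comfortably above
    the 80-byte envelopes the protocol produces.
    """
    if bits < 1024:
        raise CryptoError("modulus below 1024 bits cannot carry an envelope")
    rng = rng or random.SystemRandom()
    e = 65537
    while True:
        p = _random_prime(bits // 2, rng)
        q = _random_prime(bits - bits // 2, rng)
        if p == q:
            continue
        lam = math.lcm(p - 1, q - 1)
        if math.gcd(e, lam) != 1:
            continue
        n = p * q
        if n.bit_length() != bits:
            continue
        d = pow(e, -1, lam)
        return RSAPrivateKey(n=n, e=e, d=d, p=p, q=q)


# --- OAEP (RFC 8017 EME-OAEP, SHA-256) --------------------------------------

def _mgf1(seed: bytes, length: int) -> bytes:
    out = bytearray()
    for counter in range((length + _HLEN - 1) // _HLEN):
        out += _HASH(seed + counter.to_bytes(4, "big")).digest()
    return bytes(out[:length])


def _xor(a: bytes, b: bytes) -> bytes:
    return bytes(x ^ y for x, y in zip(a, b))


def _oaep_encode(message: bytes, k: int, rng: random.Random) -> int:
    if len(message) > k - 2 * _HLEN - 2:
        raise CryptoError(f"message of {len(message)} bytes too long for {k}-byte modulus")
    lhash = _HASH(b"").digest()
    padding = b"\x00" * (k - len(message) - 2 * _HLEN - 2)
    datablock = lhash + padding + b"\x01" + message
    seed = rng.getrandbits(8 * _HLEN).to_bytes(_HLEN, "big")
    masked_db = _xor(datablock, _mgf1(seed, k - _HLEN - 1))
    masked_seed = _xor(seed, _mgf1(masked_db, _HLEN))
    return int.from_bytes(b"\x00" + masked_seed + masked_db, "big")


def _oaep_decode(em_int: int, k: int) -> bytes:
    em = em_int.to_bytes(k, "big")
    if em[0] != 0:
        raise CryptoError("decryption error")
    masked_seed, masked_db = em[1:1 + _HLEN], em[1 + _HLEN:]
    seed = _xor(masked_seed, _mgf1(masked_db, _HLEN))
    datablock = _xor(masked_db, _mgf1(seed, k - _HLEN - 1))
    if datablock[:_HLEN] != _HASH(b"").digest():
        raise CryptoError("decryption error")
    try:
        sep = datablock.index(b"\x01", _HLEN)
    except ValueError:
        raise CryptoError("decryption error") from None
    if any(datablock[_HLEN:sep]):
        raise CryptoError("decryption error")
    return datablock[sep + 1:]


def encrypt(pub: RSAPublicKey, message: bytes, rng: random.Random | None = None) -> bytes:
    """Encrypt ``message`` for the holder of the private key.

    OAEP draws a fresh random seed per call, so two encryptions of the same
    plaintext yield different ciphertexts — the randomized-encryption
    property the protocol's envelope unlinkability rests on.
    """
    rng = rng or random.SystemRandom()
    k = pub.size_bytes
    c = pow(_oaep_encode(message, k, rng), pub.e, pub.n)
    return c.to_bytes(k, "big")


def decrypt(priv: RSAPrivateKey, ciphertext: bytes) -> bytes:
    k = priv.size_bytes
    if len(ciphertext) != k:
        raise CryptoError("ciphertext length does not match modulus")
    c = int.from_bytes(ciphertext, "big")
    if c >= priv.n:
        raise CryptoError("ciphertext out of range")
    # CRT: two half-size exponentiations instead of one full-size one
    mp = pow(c, priv.d % (priv.p - 1), priv.p)
    mq = pow(c, priv.d % (priv.q - 1), priv.q)
    h = (pow(priv.q, -1, priv.p) * (mp - mq)) % priv.p
    m = mq + h * priv.q
    return _oaep_decode(m, k)


# --- signatures (deterministic full-domain hash) -----------------------------

def _fdh(data: bytes, k: int) -> int:
    # MGF1-expanded digest over k-1 bytes keeps the representative < n
    return int.from_bytes(_mgf1(_HASH(data).digest(), k - 1), "big")


def sign(priv: RSAPrivateKey, data: bytes) -> bytes:
    """Sign ``data`` with the private key (authentication direction)."""
    k = priv.size_bytes
    s = pow(_fdh(data, k), priv.d, priv.n)
    return s.to_bytes(k, "big")


def verify(pub: RSAPublicKey, data: bytes, signature: bytes) -> bool:
    k = pub.size_bytes
    if len(signature) != k:
        return False
    s = int.from_bytes(signature, "big")
    return s < pub.n and pow(s, pub.e, pub.n) == _fdh(data, k)


# --- serialization -----------------------------------------------------------
# PEM-style armor around a base64 JSON payload. Not interoperable ASN.1/DER
# (no DER writer is available here); round-trips through key_from_pem only.

def _pem(label: str, payload: dict[str, int]) -> str:
    raw = base64.b64encode(json.dumps(payload, sort_keys=True).encode()).decode()
    lines = [raw[i:i + 64] for i in range(0, len(raw), 64)]
    return f"-----BEGIN {label}-----\n" + "\n".join(lines) + f"\n-----END {label}-----\n"


def public_key_to_pem(key: RSAPublicKey) -> str:
    return _pem("SECURELINK RSA PUBLIC KEY", {"n": key.n, "e": key.e})


def private_key_to_pem(key: RSAPrivateKey) -> str:
    return _pem("SECURELINK RSA PRIVATE KEY",
                {"n": key.n, "e": key.e, "d": key.d, "p": key.p, "q": key.q})


def key_from_pem(text: str) -> RSAPublicKey | RSAPrivateKey:
    lines = [ln.strip() for ln in text.strip().splitlines()]
    if len(lines) < 3 or not lines[0].startswith("-----BEGIN"):
        raise CryptoError("not a PEM-armored key")
    payload = json.loads(base64.b64decode("".join(lines[1:-1])))
    if "d" in payload:
        return RSAPrivateKey(**payload)
    return RSAPublicKey(**payload)
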