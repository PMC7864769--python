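"""Signature and hashing primitives for the consortium ledger.

Every trust decision in the ledger — membership, endorsement, block
authorship — reduces to a detached signature over canonical bytes.  The
scheme is ECDSA over NIST P-256 with SHA-256 digests and deterministic
nonces (RFC 6979), so signing the same message with the same key always
yields the same signature and whole-network runs are bit-reproducible
under a fixed seed.

Implemented here in pure Python on top of ``hashlib``/``hmac``: field
arithmetic uses Jacobian projective coordinates, the base point carries a
precomputed window table to keep signing fast, and verification is
memoised on (public key, digest, signature) because committing peers
re-verify identical byte strings many times.

This is an in-process trust layer for a simulated consortium, not a
hardened TLS stack; side-channel resistance is a non-goal.
"""

from __future__ import annotations

import hashlib
import hmac
import json
from functools import lru_cache
from typing import Any, Optional, Tuple

# --- NIST P-256 (secp256r1) domain parameters ---------------------------

P = 0xFFFFFFFF00000001000000000000000000000000FFFFFFFFFFFFFFFFFFFFFFFF
A = P - 3
B = 0x5AC635D8AA3A93E7B3EBBD55769886BC651D06B0CC53B0F63BCE3C3E27D2604B
N = 0xFFFFFFFF00000000FFFFFFFFFFFFFFFFBCE6FAADA7179E84F3B9CAC2FC632551
GX = 0x6B17D1F2E12C4247F8BCE6E563A440F277037D812DEB33A0F4A13945D898C296
GY = 0x4FE342E2FE1A7F9B8EE7EB4A7C0F9E162BCE33576B315ECECBB6406837BF51F5

Point = Optional[Tuple[int, int]]  # affine; None is the point at infinity
_Jac = Tuple[int, int, int]  # Jacobian (X, Y, Z); Z == 0 is infinity

_INF: _Jac = (1, 1, 0)


def _jac_double(pt: _Jac) -> _Jac:
    X1, Y1, Z1 = pt
    if Z1 == 0 or Y1 == 0:
        return _INF
    delta = Z1 * Z1 % P
    gamma = Y1 * Y1 % P
    beta = X1 * gamma % P
    alpha = 3 * (X1 - delta) * (X1 + delta) % P
    X3 = (alpha * alpha - 8 * beta) % P
    Z3 = ((Y1 + Z1) * (Y1 + Z1) - gamma - delta) % P
    Y3 = (alpha * (4 * beta - X3) - 8 * gamma * gamma) % P
    return (X3, Y3, Z3)


def _jac_add(p1: _Jac, p2: _Jac) -> _Jac:
    X1, Y1, Z1 = p1
    X2, Y2, Z2 = p2
    if Z1 == 0:
        return p2
    if Z2 == 0:
        return p1
    Z1Z1 = Z1 * Z1 % P
    Z2Z2 = Z2 * Z2 % P
    U1 = X1 * Z2Z2 % P
    U2 = X2 * Z1Z1 % P
    S1 = Y1 * Z2 * Z2Z2 % P
    S2 = Y2 * Z1 * Z1Z1 % P
    H = (U2 - U1) % P
    r = (S2 - S1) % P
    if H == 0:
        if r == 0:
            return _jac_double(p1)
        return _INF
    I = 4 * H * H % P
    J = H * I % P
    r2 = 2 * r % P
    V = U1 * I % P
    X3 = (r2 * r2 - J - 2 * V) % P
    Y3 = (r2 * (V - X3) - 2 * S1 * J) % P
    Z3 = ((Z1 + Z2) * (Z1 + Z2) - Z1Z1 - Z2Z2) % P * H % P
    return (X3, Y3, Z3)


def _to_affine(pt: _Jac) -> Point:
    X, Y, Z = pt
    if Z == 0:
        return None
    zinv = pow(Z, P - 2, P)
    zinv2 = zinv * zinv % P
    return (X * zinv2 % P, Y * zinv2 * zinv % P)


def _from_affine(pt: Point) -> _Jac:
    if pt is None:
        return _INF
    return (pt[0], pt[1], 1)


def _scalar_mult_jac(k: int, pt: _Jac) -> _Jac:
    k %= N
    acc = _INF
    add = _jac_add
    dbl = _jac_double
    for bit in bin(k)[2:]:
        acc = dbl(acc)
        if bit == "1":
            acc = add(acc, pt)
    return acc


# Fixed-base window table for G: _G_TABLE[i][j] = (j+1) * 16^i * G,
# i in 0..63, j in 0..14 (4-bit windows).  Speeds up signing ~4x.
def _build_g_table():
    table = []
    base: _Jac = (GX, GY, 1)
    for _ in range(64):
        row = []
        acc = _INF
        for _ in range(15):
            acc = _jac_add(acc, base)
            row.append(acc)
        table.append(row)
        for _ in range(4):
            base = _jac_double(base)
    return table


_G_TABLE = _build_g_table()


def _base_mult(k: int) -> _Jac:
    k %= N
    acc = _INF
    i = 0
    while k:
        nib = k & 0xF
        if nib:
            acc = _jac_add(acc, _G_TABLE[i][nib - 1])
        k >>= 4
        i += 1
    return acc


def scalar_mult(k: int, pt: Point) -> Point:
    """k * pt in affine coordinates (None = infinity)."""
    return _to_affine(_scalar_mult_jac(k, _from_affine(pt)))


def on_curve(pt: Point) -> bool:
    if pt is None:
        return True
    x, y = pt
    return (y * y - (x * x * x + A * x + B)) % P == 0


# --- key handling --------------------------------------------------------


def public_key_bytes(d: int) -> bytes:
    """Uncompressed SEC1 encoding (0x04 || x || y) of d*G."""
    pt = _to_affine(_base_mult(d))
    assert pt is not None
    return b"\x04" + pt[0].to_bytes(32, "big") + pt[1].to_bytes(32, "big")


def decode_public_key(pub: bytes) -> Point:
    if len(pub) != 65 or pub[0] != 0x04:
        raise ValueError("expected 65-byte uncompressed SEC1 public key")
    pt = (int.from_bytes(pub[1:33], "big"), int.from_bytes(pub[33:], "big"))
    if not on_curve(pt):
        raise ValueError("point not on curve")
    return pt


def derive_keypair(seed: bytes) -> Tuple[int, bytes]:
    """Deterministically derive a keypair from seed material.

    HMAC-SHA256 in counter mode until the candidate lands in [1, n-1];
    the same seed always yields the same key, which lets a whole network
    (CAs, peers, orderer, clients) be rebuilt bit-identically from one
    integer seed.
    """
    counter = 0
    while True:
        h = hmac.new(seed, b"healthledger-key:%d" % counter, hashlib.sha256)
        d = int.from_bytes(h.digest(), "big")
        if 1 <= d < N:
            return d, public_key_bytes(d)
        counter += 1


# --- deterministic ECDSA (RFC 6979) --------------------------------------


def _rfc6979_k(d: int, h1: bytes) -> int:
    """Deterministic nonce; qlen == hlen == 256 so bits2int is identity."""
    x = d.to_bytes(32, "big")
    z = (int.from_bytes(h1, "big") % N).to_bytes(32, "big")
    V = b"\x01" * 32
    K = b"\x00" * 32
    K = hmac.new(K, V + b"\x00" + x + z, hashlib.sha256).digest()
    V = hmac.new(K, V, hashlib.sha256).digest()
    K = hmac.new(K, V + b"\x01" + x + z, hashlib.sha256).digest()
    V = hmac.new(K, V, hashlib.sha256).digest()
    while True:
        V = hmac.new(K, V, hashlib.sha256).digest()
        k = int.from_bytes(V, "big")
        if 1 <= k < N:
            return k
        K = hmac.new(K, V + b"\x00", hashlib.sha256).digest()
        V = hmac.new(K, V, hashlib.sha256).digest()


def sign(d: int, message: bytes) -> bytes:
    """Detached signature: 64 bytes, r || s, big-endian."""
    h1 = hashlib.sha256(message).digest()
    e = int.from_bytes(h1, "big") % N
    k = _rfc6979_k(d, h1)
    while True:
        pt = _to_affine(_base_mult(k))
        assert pt is not None
        r = pt[0] % N
        s = pow(k, N - 2, N) * (e + r * d) % N
        if r and s:
            return r.to_bytes(32, "big") + s.to_bytes(32, "big")
        k = (k + 1) % N or 1  # vanishing r/s is astronomically unlikely


def _verify_digest(pub: bytes, h1: bytes, signature: bytes) -> bool:
    try:
        Q = decode_public_key(pub)
    except ValueError:
        return False
    if len(signature) != 64:
        return False
    r = int.from_bytes(signature[:32], "big")
    s = int.from_bytes(signature[32:], "big")
    if not (1 <= r < N and 1 <= s < N):
        return False
    e = int.from_bytes(h1, "big") % N
    w = pow(s, N - 2, N)
    u1 = e * w % N
    u2 = r * w % N
    pt = _to_affine(_jac_add(_base_mult(u1), _scalar_mult_jac(u2, _from_affine(Q))))
    if pt is None:
        return False
    return pt[0] % N == r


@lru_cache(maxsize=65536)
def _verify_cached(pub: bytes, h1: bytes, signature: bytes) -> bool:
    return _verify_digest(pub, h1, signature)


def verify(pub: bytes, message: bytes, signature: bytes) -> bool:
    """True iff ``signature`` is a valid ECDSA signature of ``message``.

    Malformed keys or signatures return False rather than raising.
    Results are memoised: committing peers re-check the same
    (key, digest, signature) triples on every replica.
    """
    return _verify_cached(bytes(pub), hashlib.sha256(message).digest(), bytes(signature))


# --- hashing and canonical JSON ------------------------------------------


def sha256_hex(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def canonical_json(obj: Any) -> bytes:
    """Canonical UTF-8 JSON: sorted keys, no insignificant whitespace.

    Semantically equal documents serialize to identical bytes regardless
    of construction order, which is what makes hashing and signing over
    JSON well defined.
    """
    return json.dumps(
        obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")
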