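"""Multi-party secure linkage workflow.

Four roles cooperate to link two (or more) person-level files without any
single party holding enough information to re-identify anyone:

* **Key-Management Authority (KMA)** — generates and distributes the two
  study-specific hashing keys: HK1 to every data producer, HK2 to the
  trusted third party. It never sees any record data.
* **Producers** — hold the cleartext records. Each assigns a *neutral*
  sequential identifier to its records, hashes the linkage identifier with
  HK1 (→ H(id)), appends a fresh random chain per record, and encrypts the
  result with the study public key. It sends (seq, ciphertext) to the
  trusted third party and (seq, payload) to the linking organization —
  never the identifiers.
* **Trusted third party (TTP)** — generates the study's asymmetric key
  pair, decrypts the envelopes, strips the random chains, re-hashes each
  H(id) with HK2 (→ DH(id)) and emits a correspondence table of neutral
  identifier pairs whose DH(id) are equal. Lacking HK1, it cannot mount a
  dictionary attack on the fingerprints it sees.
* **Linking organization** — joins the producers' payload files through
  the correspondence table. It sees neutral identifiers and payload only.

Every observation of an information class by a role is recorded in an
append-only audit trail; the trail's possession matrix is checked against
the role contracts above, and any violation aborts the run.

All roles run in one process as isolated components whose only
communication is logged message-passing; the audit trail is the
enforcement mechanism, not OS-level isolation.
"""

from __future__ import annotations

import json
import random
import secrets
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from . import crypto
from .pseudonymize import HashKey, hash_value

__all__ = [
    "CLEARTEXT_ID", "H_ID", "DH_ID", "CIPHERTEXT", "SEQ", "PAYLOAD",
    "HK1", "HK2", "PUB_E", "PRIV_E",
    "AuditEvent", "AuditTrail", "CompartmentalizationError", "ProtocolError",
    "StudyKeyring", "ProtocolConfig", "ProtocolResult",
    "KeyManagementAuthority", "kma_issue_keys", "ttp_generate_keypair",
    "producer_prepare", "ttp_resolve", "link_org_join", "run_protocol",
    "ALLOWED_POSSESSION",
]

# Information classes a role can observe
CLEARTEXT_ID = "cleartext-id"
H_ID = "H(id)"
DH_ID = "DH(id)"
CIPHERTEXT = "ciphertext"
SEQ = "seq"
PAYLOAD = "payload"
HK1 = "HK1"
HK2 = "HK2"
PUB_E = "Pub_E"
PRIV_E = "Priv_E"

#: Which information classes each role kind may ever observe. The producers
#: additionally see H(id) and ciphertext because they compute them; the TTP
#: holds Pub_E because it generated the key pair.
ALLOWED_POSSESSION: dict[str, frozenset[str]] = {
    "kma": frozenset({HK1, HK2}),
    "kma1": frozenset({HK1}),           # separate-authority variant
    "kma2": frozenset({HK2}),
    "producer": frozenset({CLEARTEXT_ID, PAYLOAD, SEQ, H_ID, CIPHERTEXT, HK1, PUB_E}),
    "ttp": frozenset({CIPHERTEXT, H_ID, DH_ID, SEQ, HK2, PRIV_E, PUB_E}),
    "linkorg": frozenset({SEQ, PAYLOAD}),
}


class ProtocolError(RuntimeError):
    """Protocol-level failure (framing, integrity, study reuse)."""


class CompartmentalizationError(ProtocolError):
    """A role observed an information class its contract forbids."""

    def __init__(self, event: "AuditEvent") -> None:
        super().__init__(
            f"role {event.role!r} observed forbidden class {event.info_class!r} "
            f"({event.note})")
        self.event = event


@dataclass(frozen=True)
class AuditEvent:
    index: int
    role: str
    info_class: str
    note: str = ""

    @property
    def role_kind(self) -> str:
        return self.role.split(":", 1)[0]


class AuditTrail:
    """Append-only record of every information observation by every role.

    ``strict=True`` (the default inside :func:`run_protocol`) checks every
    observation against :data:`ALLOWED_POSSESSION` as it happens, so a
    role-separation violation aborts mid-run at the offending event.
    """

    def __init__(self, strict: bool = True,
                 allowed: dict[str, frozenset[str]] | None = None) -> None:
        self._events: list[AuditEvent] = []
        self.strict = strict
        self.allowed = allowed or ALLOWED_POSSESSION

    def observe(self, role: str, info_class: str, note: str = "") -> None:
        event = AuditEvent(len(self._events), role, info_class, note)
        self._events.append(event)
        if self.strict and info_class not in self.allowed.get(event.role_kind, frozenset()):
            raise CompartmentalizationError(event)

    @property
    def events(self) -> tuple[AuditEvent, ...]:
        return tuple(self._events)

    def possession_matrix(self) -> dict[str, set[str]]:
        matrix: dict[str, set[str]] = {}
        for ev in self._events:
            matrix.setdefault(ev.role_kind, set()).add(ev.info_class)
        return matrix

    def verify(self) -> None:
        """Re-check the whole trail (used after non-strict runs)."""
        for ev in self._events:
            if ev.info_class not in self.allowed.get(ev.role_kind, frozenset()):
                raise CompartmentalizationError(ev)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps({"index": e.index, "role": e.role,
                                     "class": e.info_class, "note": e.note})
                         for e in self._events) + ("\n" if self._events else "")


# --- keyring and configuration ----------------------------------------------

@dataclass(frozen=True)
class StudyKeyring:
    """The study's secret material. Exists only for bookkeeping in tests;
    inside a run each component holds only its own share."""

    hk1: HashKey
    hk2: HashKey
    keypair: crypto.RSAPrivateKey


@dataclass(frozen=True)
class ProtocolConfig:
    id_field: str = "nir"
    identifier_fields: tuple[str, ...] = ("nir",)   # all dropped from payloads
    random_chain_len: int = 16                       # bytes appended to H(id)
    rsa_bits: int = 2048
    transport_rsa_bits: int = 1024                   # key-distribution messages only
    seq_mode: str = "sequential"                     # or "random"
    minimal_transfer: bool = False
    separate_authorities: bool = False
    shuffle_correspondence: bool = False

    def __post_init__(self) -> None:
        if self.random_chain_len < 1:
            raise ProtocolError("random chain length must be >= 1 byte")
        if self.id_field not in self.identifier_fields:
            raise ProtocolError("id_field must be listed among identifier_fields")


@dataclass
class ProtocolResult:
    linked: pd.DataFrame
    correspondence: list[pd.DataFrame]     # one table per successive producer pair
    audit: AuditTrail
    unmatched: dict[str, pd.DataFrame]     # producer name -> unlinked payload rows
    multi_matches: pd.DataFrame
    quarantined: dict[str, int]            # producer name -> records lacking the id


# --- key management authority -------------------------------------------------

class KeyManagementAuthority:
    """Generates, signs and archives the study-specific hashing keys.

    Key material is derived deterministically from the seed so a simulation
    reproduces exactly; a study identifier can be used only once, because
    reusing hashing keys across studies would allow unauthorized linkage of
    their outputs.
    """

    def __init__(self, rng: random.Random, kind: str = "kma") -> None:
        self.role = kind
        self._rng = rng
        self._issued: set[str] = set()
        self.signing_key = crypto.generate_keypair(1024, rng)

    def issue_keys(self, study_id: str) -> tuple[HashKey, HashKey]:
        if study_id in self._issued:
            raise ProtocolError(f"study id {study_id!r} already used; "
                                f"hashing keys must be fresh per study")
        self._issued.add(study_id)
        hk1 = HashKey(f"{study_id}/HK1", self._rng.randbytes(32))
        hk2 = HashKey(f"{study_id}/HK2", self._rng.randbytes(32))
        return hk1, hk2


def _send_key(signer: crypto.RSAPrivateKey, recipient_pub: crypto.RSAPublicKey,
              key: HashKey, rng: random.Random) -> tuple[list[bytes], bytes]:
    """Sign-then-encrypt a hashing key for one recipient.

    The signature is computed over the cleartext key message; message and
    signature both travel encrypted (chunked OAEP) under the recipient's
    transport public key.
    """
    msg = json.dumps({"key_id": key.key_id,
                      "secret": key.secret.hex()}).encode()
    sig = crypto.sign(signer, msg)
    blob = len(msg).to_bytes(4, "big") + msg + sig
    chunk = recipient_pub.max_message_bytes
    ct = [crypto.encrypt(recipient_pub, blob[i:i + chunk], rng)
          for i in range(0, len(blob), chunk)]
    return ct, sig


def _receive_key(recipient_priv: crypto.RSAPrivateKey,
                 signer_pub: crypto.RSAPublicKey,
                 ciphertexts: list[bytes]) -> HashKey:
    blob = b"".join(crypto.decrypt(recipient_priv, c) for c in ciphertexts)
    msg_len = int.from_bytes(blob[:4], "big")
    msg, sig = blob[4:4 + msg_len], blob[4 + msg_len:]
    if not crypto.verify(signer_pub, msg, sig):
        raise ProtocolError("key-distribution signature verification failed")
    payload = json.loads(msg)
    return HashKey(payload["key_id"], bytes.fromhex(payload["secret"]))


# --- protocol steps -----------------------------------------------------------

def kma_issue_keys(kma: KeyManagementAuthority, study_id: str,
                   producer_roles: Sequence[str], ttp_role: str,
                   transport_pubs: dict[str, crypto.RSAPublicKey],
                   rng: random.Random, audit: AuditTrail,
                   hk2_authority: KeyManagementAuthority | None = None,
                   ) -> dict[str, list[list[bytes]]]:
    """Step 1: distribute HK1 to every producer and HK2 to the TTP.

    Returns the encrypted key-distribution messages keyed by recipient role.
    With ``hk2_authority`` set (separate-authority variant), HK2 is issued
    and signed by the second authority instead.
    """
    hk1, hk2 = kma.issue_keys(study_id)
    if hk2_authority is not None:
        _, hk2 = hk2_authority.issue_keys(study_id + "/hk2")
    audit.observe(kma.role, HK1, "generated")
    if hk2_authority is None:
        audit.observe(kma.role, HK2, "generated")
    else:
        audit.observe(hk2_authority.role, HK2, "generated")
    messages: dict[str, list[list[bytes]]] = {}
    for role in producer_roles:
        ct, _ = _send_key(kma.signing_key, transport_pubs[role], hk1, rng)
        messages.setdefault(role, []).append(ct)
    hk2_signer = (hk2_authority or kma).signing_key
    ct, _ = _send_key(hk2_signer, transport_pubs[ttp_role], hk2, rng)
    messages.setdefault(ttp_role, []).append(ct)
    return messages


def ttp_generate_keypair(study_id: str, bits: int, rng: random.Random,
                         ttp_role: str, producer_roles: Sequence[str],
                         audit: AuditTrail) -> crypto.RSAPrivateKey:
    """Step 2: the TTP generates the study encryption key pair.

    The public part goes to every producer; the private part never leaves
    the TTP, and the KMA is never shown either part.
    """
    keypair = crypto.generate_keypair(bits, rng)
    audit.observe(ttp_role, PRIV_E, f"generated for study {study_id}")
    audit.observe(ttp_role, PUB_E, "generated")
    for role in producer_roles:
        audit.observe(role, PUB_E, "received from TTP")
    return keypair


def producer_prepare(records: pd.DataFrame, hk1: HashKey,
                     pub_e: crypto.RSAPublicKey, r: int,
                     config: ProtocolConfig, role: str,
                     rng: random.Random, audit: AuditTrail,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Steps 3–4 and 7, from one producer's point of view.

    Returns ``(envelopes, payload, n_quarantined)`` where envelopes has
    columns ``seq`` and ``ciphertext`` (hex) and payload carries ``seq``
    plus every non-identifier column. Records lacking the linkage
    identifier are quarantined (counted, excluded from both outputs).
    """
    audit.observe(role, CLEARTEXT_ID, f"{len(records)} source records")
    audit.observe(role, PAYLOAD, "source records")
    audit.observe(role, HK1, "received from KMA")
    audit.observe(role, PUB_E, "received from TTP")

    idf = config.id_field
    if idf not in records.columns:
        raise ProtocolError(f"producer {role}: identifier column {idf!r} missing")
    present = records[idf].notna() & (records[idf].astype(str) != "")
    quarantined = int((~present).sum())
    usable = records.loc[present].reset_index(drop=True)

    if "seq" in usable.columns:  # neutral ids already assigned upstream
        seqs = usable["seq"].tolist()
        if len(set(seqs)) != len(seqs):
            raise ProtocolError(f"producer {role}: pre-assigned seq values not unique")
        usable = usable.drop(columns=["seq"])
    elif config.seq_mode == "random":
        seqs = rng.sample(range(1, max(10 * len(usable), 100) + 1), len(usable))
    else:
        seqs = list(range(1, len(usable) + 1))
    audit.observe(role, SEQ, "assigned neutral identifiers")

    ciphertexts = []
    for value in usable[idf].astype(str):
        h = hash_value(value, hk1)
        chain = rng.randbytes(r)  # fresh per record: equal H(id) -> unequal ciphertext
        plaintext = h.hex.encode("ascii") + chain
        ciphertexts.append(crypto.encrypt(pub_e, plaintext, rng).hex())
    audit.observe(role, H_ID, "computed H(id) with HK1")
    audit.observe(role, CIPHERTEXT, "encrypted envelopes")

    envelopes = pd.DataFrame({"seq": seqs, "ciphertext": ciphertexts})
    payload_cols = [c for c in usable.columns if c not in config.identifier_fields]
    payload = usable[payload_cols].copy()
    payload.insert(0, "seq", seqs)
    return envelopes, payload, quarantined


def _resolve_envelopes(envelopes: pd.DataFrame, priv_e: crypto.RSAPrivateKey,
                       hk2: HashKey, r: int) -> tuple[pd.DataFrame, int]:
    rows = []
    rejected = 0
    for seq, ct_hex in zip(envelopes["seq"], envelopes["ciphertext"]):
        try:
            plaintext = crypto.decrypt(priv_e, bytes.fromhex(ct_hex))
        except crypto.CryptoError:
            rejected += 1
            continue
        if len(plaintext) != 64 + r:
            raise ProtocolError(
                f"malformed envelope plaintext: {len(plaintext)} bytes, expected {64 + r}")
        h_hex = plaintext[:-r].decode("ascii")
        dh = hash_value(h_hex, hk2)
        rows.append({"seq": seq, "dh": dh.hex})
    return pd.DataFrame(rows, columns=["seq", "dh"]), rejected


def ttp_resolve(envelopes_a: pd.DataFrame, envelopes_b: pd.DataFrame,
                priv_e: crypto.RSAPrivateKey, hk2: HashKey, r: int,
                role: str, audit: AuditTrail,
                shuffle: bool = False, rng: random.Random | None = None,
                ) -> tuple[pd.DataFrame, int]:
    """Steps 5–6: decrypt envelopes, double-hash, emit the correspondence table.

    Each envelope is decrypted with Priv_E, the trailing ``r`` random bytes
    are stripped, and the recovered H(id) is re-hashed with HK2 into DH(id).
    The table lists every (seq_a, seq_b) whose DH(id) are equal;
    multi-matches are preserved. Only neutral identifiers leave this role.
    """
    audit.observe(role, HK2, "received from KMA")
    audit.observe(role, CIPHERTEXT, "received envelopes")
    audit.observe(role, SEQ, "received neutral identifiers")
    resolved_a, rej_a = _resolve_envelopes(envelopes_a, priv_e, hk2, r)
    resolved_b, rej_b = _resolve_envelopes(envelopes_b, priv_e, hk2, r)
    audit.observe(role, H_ID, "decrypted H(id)")
    audit.observe(role, DH_ID, "computed DH(id) with HK2")
    table = resolved_a.rename(columns={"seq": "seq_a"}).merge(
        resolved_b.rename(columns={"seq": "seq_b"}), on="dh")[["seq_a", "seq_b"]]
    table = table.sort_values(["seq_a", "seq_b"], kind="stable").reset_index(drop=True)
    if shuffle:
        table = table.sample(frac=1.0, random_state=(rng or random).randrange(2**31)
                             ).reset_index(drop=True)
    return table, rej_a + rej_b


def link_org_join(table: pd.DataFrame, payload_a: pd.DataFrame,
                  payload_b: pd.DataFrame, role: str, audit: AuditTrail,
                  suffixes: tuple[str, str] = ("_a", "_b"),
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Step 8: join the payload files through the correspondence table.

    Returns ``(linked, unmatched_a, unmatched_b, multi)``. Unmatched rows
    (no correspondence) and multi-matched rows (several correspondences)
    are reported separately — both situations are legitimate and their
    treatment depends on the study.
    """
    audit.observe(role, SEQ, "received correspondence table")
    audit.observe(role, PAYLOAD, "received payload files")
    missing_a = set(table["seq_a"]) - set(payload_a["seq"])
    missing_b = set(table["seq_b"]) - set(payload_b["seq"])
    if missing_a or missing_b:
        side = "A" if missing_a else "B"
        raise ProtocolError(f"correspondence table references seq values absent "
                            f"from producer {side}'s payload file")
    linked = (table
              .merge(payload_a.rename(columns={"seq": "seq_a"}), on="seq_a")
              .merge(payload_b.rename(columns={"seq": "seq_b"}), on="seq_b",
                     suffixes=suffixes)
              .sort_values(["seq_a", "seq_b"], kind="stable")
              .reset_index(drop=True))
    unmatched_a = payload_a[~payload_a["seq"].isin(table["seq_a"])].reset_index(drop=True)
    unmatched_b = payload_b[~payload_b["seq"].isin(table["seq_b"])].reset_index(drop=True)
    counts_a = table["seq_a"].value_counts()
    counts_b = table["seq_b"].value_counts()
    multi_mask = (table["seq_a"].map(counts_a) > 1) | (table["seq_b"].map(counts_b) > 1)
    multi = table[multi_mask].reset_index(drop=True)
    return linked, unmatched_a, unmatched_b, multi


def run_protocol(producer_files: dict[str, pd.DataFrame],
                 config: ProtocolConfig | None = None,
                 seed: int | None = None,
                 study_id: str = "study-1",
                 strict_audit: bool = True) -> ProtocolResult:
    """Execute the complete eight-step workflow over two or more producers.

    With more than two producers, correspondence tables are built pairwise
    between successive producers and the linked dataset is the chained
    inner join. ``minimal_transfer`` restricts each payload file to the
    seq values that appear in a correspondence table before it is sent to
    the linking organization.
    """
    config = config or ProtocolConfig()
    if len(producer_files) < 2:
        raise ProtocolError("at least 2 producers are required")
    rng = random.Random(seed) if seed is not None else random.Random(secrets.randbits(63))
    audit = AuditTrail(strict=strict_audit)

    names = list(producer_files)
    producer_roles = [f"producer:{n}" for n in names]
    ttp_role, linkorg_role = "ttp:1", "linkorg:1"

    # transport keys (secure-channel stand-in for key distribution)
    transport = {role: crypto.generate_keypair(config.transport_rsa_bits, rng)
                 for role in producer_roles + [ttp_role]}
    transport_pubs = {role: kp.public for role, kp in transport.items()}

    # step 1 — hashing keys
    kma = KeyManagementAuthority(rng, kind="kma1" if config.separate_authorities else "kma")
    kma2 = KeyManagementAuthority(rng, kind="kma2") if config.separate_authorities else None
    key_msgs = kma_issue_keys(kma, study_id, producer_roles, ttp_role,
                              transport_pubs, rng, audit, hk2_authority=kma2)
    hk1_by_producer = {
        role: _receive_key(transport[role], kma.signing_key.public, key_msgs[role][0])
        for role in producer_roles}
    hk2 = _receive_key(transport[ttp_role], (kma2 or kma).signing_key.public,
                       key_msgs[ttp_role][0])

    # step 2 — study encryption key pair
    keypair = ttp_generate_keypair(study_id, config.rsa_bits, rng,
                                   ttp_role, producer_roles, audit)

    # steps 3–4 and 7 — producers
    envelopes, payloads, quarantined = {}, {}, {}
    for name, role in zip(names, producer_roles):
        env, pay, quar = producer_prepare(
            producer_files[name], hk1_by_producer[role], keypair.public,
            config.random_chain_len, config, role, rng, audit)
        envelopes[name], payloads[name], quarantined[name] = env, pay, quar

    # steps 5–6 — TTP resolves successive producer pairs
    tables = []
    for left, right in zip(names[:-1], names[1:]):
        table, _ = ttp_resolve(envelopes[left], envelopes[right], keypair, hk2,
                               config.random_chain_len, ttp_role, audit,
                               shuffle=config.shuffle_correspondence, rng=rng)
        tables.append(table)

    # step 7 transfer — optionally only rows that appear linked
    sent_payloads = {}
    for i, name in enumerate(names):
        pay = payloads[name]
        if config.minimal_transfer:
            linked_seqs: set = set()
            if i > 0:
                linked_seqs |= set(tables[i - 1]["seq_b"])
            if i < len(tables):
                linked_seqs |= set(tables[i]["seq_a"])
            pay = pay[pay["seq"].isin(linked_seqs)].reset_index(drop=True)
        sent_payloads[name] = pay

    # step 8 — linking organization
    linked, un_a, un_b, multi = link_org_join(
        tables[0], sent_payloads[names[0]], sent_payloads[names[1]],
        linkorg_role, audit,
        suffixes=(f"_{names[0]}", f"_{names[1]}"))
    unmatched = {names[0]: un_a, names[1]: un_b}
    for i in range(1, len(tables)):  # chain further producers onto the spine
        nxt = names[i + 1]
        step = tables[i].rename(columns={"seq_a": f"seq_{names[i]}", "seq_b": "seq_b_next"})
        linked = linked.rename(columns={"seq_a": f"seq_{names[0]}",
                                        "seq_b": f"seq_{names[i]}"})
        linked = (linked.merge(step, on=f"seq_{names[i]}")
                  .merge(sent_payloads[nxt].rename(columns={"seq": "seq_b_next"}),
                         on="seq_b_next")
                  .rename(columns={"seq_b_next": f"seq_{nxt}"}))

    if not strict_audit:
        audit.verify()
    return ProtocolResult(linked=linked, correspondence=tables, audit=audit,
                          unmatched=unmatched, multi_matches=multi,
                          quarantined=quarantined)
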