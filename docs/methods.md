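# Methods

`securelink` implements a privacy-preserving record-linkage workflow for
administrative and health files: keyed one-way pseudonymization of
identifiers, Fellegi–Sunter probabilistic matching with EM-estimated
weights, and a simulated multi-party protocol that splits knowledge across
a Key-Management Authority, data producers, a trusted third party and a
linking organization. This note records the models, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Pseudonymization

Identifier values are fingerprinted with SHA-256 after UTF-8 encoding. A
secret hashing key (salt) is concatenated to the value — by default as a
suffix, which is the variant that reproduces the well-known
`SHA256("DupontXZ!#45")` example; prefix mode is available. The algorithm
is fixed: SHA-256 is the current recommendation of the French national
information-security agency (ANSSI), and weaker digests (MD5, SHA-1) are
deliberately not offered. Double hashing composes two keyed hashes,
`DH(x) = H(H(x, HK1), HK2)`, where the intermediate value hashed by the
second key is the 64-character lowercase hex fingerprint. All four
published example fingerprints (salted and unsalted) reproduce exactly
under UTF-8 suffix salting, so no encoding caveat is needed.

A per-record salt derivation (HMAC-SHA256 of a record field under a master
key) is provided for storage pseudonymization only; it must never be
applied to linkage fields, because distinct salts destroy cross-file
linkability by design.

The block-hash similarity splits a normalized string into consecutive
`n`-character blocks, hashes each block separately, and scores the fraction
of block positions with equal fingerprints. The denominator is the block
count of the **longer** string — a deliberate choice (no formula is
published) that penalizes length mismatches instead of ignoring them.

## Normalization

Hashed comparison is all-or-nothing, so entry variation must be collapsed
before hashing: lowercasing, accent stripping (NFD decomposition, then
removal of combining marks — deterministic and locale-independent),
non-alphabetic stripping, American Soundex (letter + 3 digits; the
canonical published rule set, since no variant is specified in the
literature we follow), and date canonicalization to ISO `YYYY-MM-DD` from a
configurable dialect (default day/month/year, the convention of the worked
examples). Plans are idempotent by construction: a valid Soundex code and
an ISO date are fixed points of their transforms. Dates are hashed as one
field by default; component-wise hashing (day, month, year separately) can
be had by declaring the components as separate fields.

## Fellegi–Sunter linkage

Record pairs are modelled as a two-class latent mixture: M (same person)
and U (different persons). Field `i` agrees with probability `m_i` in class
M and `u_i` in class U; agreement is binary equality, which behaves
identically on cleartext and hashed values. Unit weights are
`log(m_i/u_i)` on agreement and `log((1-m_i)/(1-u_i))` on disagreement;
under conditional independence given the class they are log likelihood
ratios and sum into the compound weight. Logarithm base defaults to 2 (the
record-linkage convention); changing base rescales all weights uniformly.

**EM.** Pattern counts are fitted by EM for the two-class
conditional-independence model. E-step: posterior match probability per
pattern from the current `(m, u, p)`. M-step: `p` becomes the
posterior-weighted match fraction; `m_i`/`u_i` become posterior-weighted
agreement rates per class, clamped to `[1e-6, 1-1e-6]` to keep weights
finite. Default initialization `m_i = 0.9`, `u_i = 0.1`, `p = 0.01`.
Convergence compares the observed-data log-likelihood after a full E+M
cycle against the pre-cycle value; when the improvement is below `tol`
(default `1e-6`) the **pre-cycle** parameters are returned — so
`tol = inf` returns the initialization after one cycle, and the discarded
final half-step is below `tol` in likelihood by construction. Reaching
`max_iter` (default 500) flags the result non-converged rather than
raising. The likelihood is symmetric under swapping the classes; fits
where most fields end with `m_i < u_i` are canonicalized by swapping
`(m, u)` and replacing `p` with `1 - p`.

**Missing values.** A field missing on either side contributes neither
agreement nor disagreement (weight 0, excluded from the EM likelihood for
that pattern); a strict mode counts missing as disagreement. This is a
package choice — the sources are silent.

**Classification.** Two thresholds split the weight axis into unmatched /
indecision / matched. A weight exactly on a threshold goes to the higher
category; boundary behaviour is not defined in the sources. Thresholds are
user-supplied (they are chosen ad hoc per study); a helper derives them
from target posterior probabilities using the per-pattern diagnostics
table. One published diagnostics table prints weight "1.4" for the
pattern agreeing only on date of birth, where its own unit-weight table
sums to −2.8 − 3.5 + 10.3 = 4.0; this package trusts the arithmetic.
Note also that the published per-field weights themselves come from a fit
on an unpublished hospital file: the tests reproduce the printed *sums*
given those weights as inputs, not the weights themselves.

**Blocking.** Candidate pairs are the union of successive blocking passes,
each contributing pairs that agree exactly on all of that pass's fields;
rows with a missing blocking value are skipped within the pass. An empty
plan degenerates to the full cartesian product with a warning above a
configurable cap. Pair output is sorted lexicographically by the neutral
identifiers for reproducibility.

## Multi-party protocol

The eight-step workflow is simulated in one process; roles are isolated
components whose only interaction is logged message-passing, and the
append-only audit trail is the enforcement mechanism (not OS isolation).
Each observation of an information class (cleartext identifier, H(id),
DH(id), ciphertext, neutral identifier, payload, HK1, HK2, Pub_E, Priv_E)
by a role is audited, and in strict mode checked immediately against the
role contracts: producers never see HK2/Priv_E; the TTP never sees
cleartext identifiers, HK1 or payload; the linking organization sees only
neutral identifiers and payload; the KMA sees only the two hashing keys.
A separate-authority variant gives HK1 and HK2 to two distinct
authorities, removing the single party that could double-hash a dictionary.

Envelopes are `C_PubE(H(id) || random)`: the 64-byte hex fingerprint plus a
fresh random chain of `r` bytes (default 16 — long enough that chain
collisions are negligible, short enough to fit one RSA-OAEP block),
encrypted under the study public key. OAEP is itself randomized, so
unlinkability of two envelopes of the same person holds twice over. The
TTP strips exactly `r` trailing bytes after decryption; `r` is distributed
to producers and TTP through the study configuration (the sources do not
say how the TTP learns it — this is the documented assumption).

Asymmetric encryption is RSA-OAEP (SHA-256/MGF1) with full-domain-hash
signatures, implemented in-package on Python integers because no
cryptography library is available in the target environment. The plaintext
fits one block at the default 2048-bit modulus, so no hybrid session-key
layer exists. Key generation is deterministic given the run seed, making
whole protocol runs byte-reproducible. Key-distribution messages from the
KMA are signed over the cleartext, then message and signature are
encrypted (chunked OAEP) under per-role transport keys (1024-bit, adequate
for 32-byte secrets in a simulation); signature verification failure
aborts the run. This implementation is simulation-grade: correct
arithmetic and padding, no side-channel hardening.

More than two producers are handled by pairwise correspondence tables
between successive producers and a chained join; the published workflow
shows exactly two. "Minimal transfer" mode sends only payload rows whose
neutral identifiers appear in a correspondence table. The correspondence
table can optionally be shuffled before transmission (off by default).

## Synthetic data

The generator emulates French-style civil identifiers: name pools with
accented forms (to exercise normalization), sex, birth dates 1920–2005,
and a 13-digit national-number body embedding sex/year/month/department/
commune/order digits plus the 2-digit control key `97 - (body mod 97)`.
Corsican department codes (2A/2B) are excluded to keep the body numeric —
a documented limitation. Producer files share an `overlap` fraction of
persons (default 0.6); each file copy is corrupted independently per field:
substitution/transposition/deletion/insertion typos, wholesale family-name
changes, blanked fields, and day/month swaps. Payload columns differ by
producer (hospitalization attributes vs vital-status attributes, after the
classic hospital-mortality linkage use case). Ground truth is person-level;
record-pair truth is derived from it.

What a green test establishes: the pipeline's algebra and the protocol's
information flow are correct on files whose error processes are
independent, per-field, and known. What it does not establish: performance
on real files with correlated errors (households, transcription habits),
realistic name-frequency distributions (the pools are small and uniform,
so u-probabilities are higher than in real populations), or time-varying
identifiers.

The scorer uses the standard confusion vocabulary: a missed true pair is a
*duplicate* (false negative), a wrongly linked pair a *collision* (false
positive); indecision pairs are tallied separately and count against
recall.

## Known limitations

- The PEM key containers are package-specific armor (base64 JSON), not
  interoperable ASN.1/DER.
- No network transport, PKI, or HSM integration; role isolation is audited,
  not enforced by the OS.
- No cleartext string-distance comparators (edit distances are unavailable
  on hashed fields anyway) and no frequency-scaled per-value weights.
- One-to-one assignment optimization over multi-matches is out of scope;
  multi-matches are preserved and flagged.
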