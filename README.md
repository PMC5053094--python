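# securelink

Privacy-preserving record linkage for administrative and health files.

Statistical studies often need to join person-level files held by
different institutions (hospital stays with mortality registers, survey
microdata with claims data), but the identifiers that make the join
possible — national numbers, names, birth dates — are exactly what privacy
law forbids circulating. `securelink` implements the standard answer to
this tension, end to end:

- **Keyed pseudonymization** — identifiers are replaced by salted SHA-256
  fingerprints `H(x) = SHA256(x ‖ key)`, irreversible yet equality-
  preserving, with *double hashing* `DH(x) = H(H(x, HK1), HK2)` so that no
  single party holds both the data and the full key material. Upstream
  normalization (case folding, accent stripping, Soundex, date
  canonicalization) absorbs entry variation before hashing.
- **Fellegi–Sunter probabilistic linkage** — record pairs belong to a
  latent match class M or unmatch class U; each comparison field *i*
  carries agreement probabilities *m<sub>i</sub>* = P(agree | M) and
  *u<sub>i</sub>* = P(agree | U), estimated by EM. The decision statistic
  is the compound weight ∑ log(m<sub>i</sub>/u<sub>i</sub>) over agreeing
  fields plus ∑ log((1−m<sub>i</sub>)/(1−u<sub>i</sub>)) over disagreeing
  ones, classified against two thresholds into matched / indecision /
  unmatched. Blocking keeps the candidate-pair count tractable, and strict
  deterministic linkage (equality join on a doubly hashed identifier) is
  available when a reliable common identifier exists.
- **A multi-party protocol simulation** — a Key-Management Authority
  distributes study-specific hashing keys; producers send encrypted
  envelopes `C_PubE(H(id) ‖ random)` keyed by neutral sequential
  identifiers; a trusted third party decrypts, double-hashes, and emits a
  correspondence table of neutral identifiers; a linking organization
  joins payloads through that table. An append-only audit trail proves
  that every role saw only what its contract allows.
- **A synthetic-data generator** — French-style populations with
  checksum-valid national numbers and configurable error processes
  (typos, name changes, missing fields, date swaps), with person-level
  ground truth for exact scoring.

## Worked example

The classic three-field illustration — family name, first name, date of
birth, with published unit weights +8.4/+5.7/+10.3 on agreement and
−2.8/−3.5/−3.1 on disagreement:

```python
from securelink import fellegi_sunter as fs

weights = fs.UnitWeightTable.from_values((8.4, 5.7, 10.3), (-2.8, -3.5, -3.1))
a = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/01/1940"}
b = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/03/1940"}
pattern = fs.agreement_pattern(a, b, ("family_name", "first_name", "birth_date"))
weight = fs.compound_weight(pattern, weights)
print("pattern:", "".join(map(str, pattern)), "weight:", round(weight, 1),
      "->", fs.classify(weight, lower=11, upper=15.2))
```

prints

```
pattern: 110 weight: 11.0 -> indecision
```

— the two records agree on both names, disagree on the birth date
(+8.4 +5.7 −3.1 = 11), and a weight of 11 falls between the thresholds:
too plausible to discard, not safe enough to link automatically.

A full protocol run on synthetic producer files:

```python
from securelink import synthdata, protocol as proto

pop = synthdata.generate_population(500, seed=7)
file_a, file_b, truth = synthdata.make_producer_files(
    pop, synthdata.ErrorConfig(overlap=0.6), seed=7)
cfg = proto.ProtocolConfig(
    id_field="nir",
    identifier_fields=("nir", "family_name", "first_name", "birth_date", "person_id"))
result = proto.run_protocol({"A": file_a, "B": file_b}, cfg, seed=7)
print("linked rows:", len(result.linked), "| true pairs:", len(truth))
```

prints

```
linked rows: 300 | true pairs: 300
```

and `result.linked` contains only neutral identifiers and payload columns
(`seq_a, seq_b, admission_year, length_of_stay, vital_status, ...`) — no
name, national number or fingerprint survives to the linked output, and
`result.audit.possession_matrix()` shows each role's information diet.

The same workflow is available from the shell:

```sh
securelink generate --n 10000 --overlap 0.6 --seed 42 \
    --out-a a.csv --out-b b.csv --truth truth.csv
securelink pseudonymize --in a.csv --field nir --key-file hk1.key --out hashed.csv
securelink link --a a.csv --b b.csv --config study.yaml \
    --out decisions.csv --diagnostics patterns.csv
securelink protocol run --config study.yaml --producers a.csv b.csv \
    --out linked.csv --audit audit.jsonl
securelink evaluate --decisions decisions.csv --truth truth.csv
```

Exit codes: 0 success, 2 configuration error, 3 protocol or
compartmentalization violation, 4 data-integrity error.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline reference
quantity from scratch — it rebuilds the worked record pair above, derives
its agreement pattern by field-wise equality, and sums the published unit
weights into the compound weight — and writes the result as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model details, numerical choices and known
limitations.
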