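# Crystal structures (user-provided)

Place the public PDB entries here, named `<ID>.pdb`, to enable the
ensemble reproduction in `tests/test_acceptance.py` and the ensemble
section of `scripts/acceptance.py`:

CAP: 1CGP 1G6N 1HW5 1I5Z 1I6X 1J59 1O3T 1RUN 1RUO 1ZRC 1ZRD 1ZRF 2GZW 4HZF
GlxR: 3R6S

For example:

```bash
for id in 1CGP 1G6N 1HW5 1I5Z 1I6X 1J59 1O3T 1RUN 1RUO 1ZRC 1ZRD 1ZRF 2GZW 4HZF 3R6S; do
  curl -sO https://files.rcsb.org/download/$id.pdb
done
```

Only doubly cAMP-bound entries enter the cooperativity ensemble (the apo
and singly bound networks are derived from them by deleting ligand nodes);
structures without two CMP instances are skipped automatically.
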