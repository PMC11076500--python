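# External reference inputs (not redistributed)

Three acceptance-level tests compare against published reference data that
this repository does not redistribute. To run them, fetch the files below
into this directory (network required); without them those tests fail with a
pointer here, while everything else runs on synthetic data.

```sh
# deposited fibril models
curl -o 8CI8.cif https://files.rcsb.org/download/8CI8.cif
curl -o 7Q64.cif https://files.rcsb.org/download/7Q64.cif

# human Nup98, residues 1-384 (the FG-repeat domain); the full-length
# UniProt record is fine — the test truncates to the first 384 residues
curl -o P52948_1-384.fasta https://rest.uniprot.org/uniprotkb/P52948.fasta
```
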