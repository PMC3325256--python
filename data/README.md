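# Optional real-structure inputs

The self-contained test suite and `scripts/acceptance.py` run entirely
on generated synthetic data. The checks against published reference
values additionally need these public files, which are not
redistributed here:

- `1WUL.pdb` — the 1.50 Å crystal structure of the reduced [NiFe]
  hydrogenase of *Desulfovibrio vulgaris* Miyazaki F:
  <https://files.rcsb.org/download/1WUL.pdb>
- `hynl_thiocapsa.fasta` — the *Thiocapsa roseopersicina* HynL large
  subunit protein sequence (the *hynL* gene product, from
  UniProt/GenBank).
- `hynb_dvulgaris.fasta` — the *D. vulgaris* Miyazaki F [NiFe]
  hydrogenase large subunit sequence (for example the SEQRES of PDB
  1WUL chain L, extractable with `seqkit` or Biopython).

Place them in this directory and rerun the suite.
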