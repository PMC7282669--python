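# File formats

All artifacts written by the package begin with comment lines recording the
package version, a hash of the generating configuration and the RNG seed.

## Model parameter files

* `*.params` — flat `key = value` text, `#` comments.  Keys: `eps_hb`,
  `n_beta`, `steric_penalty`, `alpha`, `t0`.
* Pair-energy matrix — whitespace-delimited 20×20 table with one header row
  and one label column, residues ordered `ACDEFGHIKLMNPQRSTVWY`.
* Solvent-energy vector / surface-area table — two columns: residue, value.

## Trajectories (`amylattice simulate --out`)

TSV, one row per retained sample: `temperature, sweep, c_ext,
native_fraction, c_h_exposed, e_hb, e_steric, e_state, e_aa, phi_solvent,
total, e_int, enthalpy_est`.

## Configurations (`--snapshots`)

Plain text; a header line `# amylattice system box=... n_seed=...
sequence=... seed_origin=... n_layers=...` followed by one residue per
line: `chain_id  residue_index  x  y  z  side_dir  beta_flag`
(side_dir indexes the axis directions +x,−x,+y,−y,+z,−z).

## Experimental-style data

* ITC curves — TSV with header `temperature_K, delta_H_kJ_per_mol[, sigma]`.
* Depolymerisation curves — TSV with header `denaturant_M, fraction_monomer`.
* Fibril-core sequences — FASTA (lowercase normalised to uppercase).
* Meta-analysis records — TSV with header `label, gamma, a_h`.

## Results

Fits and derived quantities are written as JSON objects with a `record`
field plus `config_hash` / `rng_seed` provenance fields; curves, state
diagrams and landscapes as TSV tables.
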