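# neurofields

Forward modeling and analysis of the extracellular signals of spiking
neurons, for both sensing modalities: electrical potentials (line-source
model of transmembrane currents) and magnetic fields (compartmental
Biot-Savart sum over axial currents). On top of the forward models the
package provides the analyses that compare the two modalities:

- **morphology** — ball-stick and branched synthetic cells, SWC
  import/export, flattening into a z-band, rigid in-plane transforms.
- **currents** — closed-form cylinder-model current densities from a
  membrane-potential profile, sign-reversal counting, and a prescribed
  traveling-wave compartmental scheme with exact current conservation.
- **fields** — Biot-Savart magnetic fields (pT), line-source potentials
  (uV, reference at infinity), current-dipole check, power-law scaling
  fits, supra-threshold signal area.
- **templates** — spike templates on sensor arrays, rotation by
  K-nearest inverse-distance resampling, rotation-averaged spread
  templates, translated cosine-similarity maps, effective radius.
- **discrimination** — flattened-template channel matrices, condition
  number, bootstrap capacity estimation.
- **recordings** — Poisson spike trains with refractory deletion,
  multimodal recording assembly with modality power equalization,
  thermal-noise helpers, spike-train match scoring.
- **reconstruction** — polarity-boundary morphology estimation from Bz
  templates: single-shot SVM boundary (GNBE) and the second-pass
  near-soma correction (CNBE), plus reconstruction-error metrics.

Units: um, ms, nA; potentials in uV, magnetic fields in pT. The sensor
plane is z = 0 and cells occupy z > 0.

## CLI

Every subcommand takes `--config` (YAML/JSON), `--seed`, `--out`,
`--dry-run`, `--log-level`:

```sh
neurofields fixtures --out fixtures          # example config + toy SWC
neurofields make-template --config cfg.yaml --out out/
neurofields simulate-fields --out out/
neurofields condition --config cfg.yaml --seed 1 --out out/
neurofields generate-recording --config cfg.yaml --out out/
neurofields reconstruct --config cfg.yaml --out out/
neurofields evaluate-sort --predicted pred.json --truth truth.json
```

Outputs are CSV tables, HDF5 template containers, JSON probe maps and
flat float32 binary recordings, with provenance (config hash, package
version) in `result.json`.

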