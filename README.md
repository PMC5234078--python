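# memims

A toolkit for the computational side of native ion-mobility mass
spectrometry of membrane proteins and the companion analysis of
lipid–protein geometry in MD-style coordinate trajectories:

- **`memims.lipidchem`** — lipid species (PE, PG, CDL, MAG) from class +
  total acyl composition `n:d`, average/monoisotopic masses, assignment of
  observed adduct masses to compositions, homologous-series spacing.
- **`memims.msdecon`** — charge-state envelope deconvolution of profile
  spectra, oligomer/adduct assignment, adduct-occupancy profiles,
  titration classification (saturating vs non-specific) and gas-phase
  dissociation curves (CV50, stability ranking).
- **`memims.imccs`** — traveling-wave ion-mobility CCS calibration
  (power law on corrected arrival times), collision-induced-unfolding
  fingerprints over (lab-frame energy × CCS), unfolding metrics: onset,
  midpoint, percent expansion, state count, two-state vs gradual
  classification, stabilization shifts with censoring.
- **`memims.structccs`** — Monte-Carlo projection-approximation collision
  cross-sections of atomic structures (PDB input) with a
  trajectory-method scale factor; trajectory-averaged CCS over a trailing
  window; CCS with/without bound ligands.
- **`memims.memtraj`** — frame alignment, lipid–protein contact detection
  (2.15 Å criterion), heavy-clash removal (0.5 Å), leaflet assignment,
  annular-shell selection with per-leaflet counts, 3-D Gaussian KDE of
  phosphate positions with OpenDX export (2×10⁻⁵ nm⁻³ rendering cutoff),
  membrane thickness maps, geometric hydrogen-bond statistics.
- **`memims.synthgen`** — deterministic synthetic generators for all of
  the above with planted ground truth (spectra, CIU surfaces, bilayers
  with planted shells/depressions/H-bonds, toy structures).
- **`memims.workflow`** — end-to-end demonstration workflows emitting
  JSON reports.

## CLI

All functionality is under a single `memims` entry point:

```bash
memims lipid-mass CDL 70:3                 # formula + masses
memims assign-adduct 1430 CDL              # composition assignment
memims ccs compute FILE.pdb --probe 1.0 --scale 1.14 --seed 1
memims ciu fit CALIBRANTS.tsv
memims ciu metrics ATDS.tsv --charge 11 --mass 82450 --cal-a A --cal-b B
memims traj contacts|shell|density|thickness|hbonds TRAJ.pdb
memims synth spectrum|ciu|membrane|structure OUTDIR --seed N
memims run --config config.json --out report.json
```

`memims synth *` writes the same plain-text formats the analysis commands
read (two-column spectra with `# key=value` headers, ATD tables,
multi-MODEL PDB trajectories) plus a ground-truth JSON sidecar.

## Notes on conventions

- Cardiolipin masses are reported for the singly deprotonated ([M−H])
  form by default, matching the convention of bacterial lipidomics
  tables; all classes also expose the neutral free acid
  (`form="free_acid"`). Assignment carries a documented ±0.5 Da
  tolerance for protonation/salt-form ambiguity.
- Lab-frame activation energy is charge × collision voltage (eV).
- Coordinates are Å; densities are emitted in nm⁻³ (1 nm⁻³ = 10⁻³ Å⁻³).
- The crystal-structure CCS consistency check
  (`tests/test_acceptance.py::TestCriterion3CrystalStructureCcs`) needs
  the reference structure PDB 4BWZ; it is fetched on first use or read
  from `data/4BWZ.pdb` / `$MEMIMS_4BWZ_PDB`. Without network access and
  without a local copy that test fails by design.
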