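# piliagg

Why do bacteria whose adhesive pili are spread over the whole cell surface
build large multicellular aggregates, while cells that bundle the same pili
into one polar patch stay in small groups?  `piliagg` is a desk-scale
in-silico assay for that question, aimed at microbial biophysicists who want
to test how the *geometry* of cell-surface adhesion shapes biofilm-like
architecture without touching a wet lab: it simulates suspensions of
adhesin-decorated cells, squeezes the end states under a virtual agar pad,
and measures aggregate size from the resulting images with a spatial
autocorrelation statistic.

## Model and statistic

Each cell is a rigid body: a repulsive body sphere (radius σ_B = 5, WCA
potential, ε = 1, k_BT = 1) decorated with 19 adhesin spheres (radius
σ_P = 1, the unit length) tangent to its surface — either hexagonally packed
into one patch (**localized**, wild-type-like polar pili) or spread
uniformly (**dispersed**, delocalized-pili mutant).  Adhesins on different
cells bind through a soft cosine well

    E_PP(r) = A [1 + cos(π r / r_c)],   r < r_c = σ_P,

with A = −8 (adhesive) or A = 0 (non-adhesive control, i.e. no functional
pilin).  Cells move by rigid-body Langevin (BAOAB) dynamics, dt = 0.05 τ,
where τ is the time a free adhesin-sized sphere needs to diffuse one unit
length.  After equilibration, configurations are compressed along z between
two repulsive plates, projected onto the x-y plane as a binary field
φ ∈ {0,1}, and quantified by the radially averaged autocorrelation

    C(r) = ⟨φ(0) φ(r)⟩ / ⟨φ²⟩  fitted as  C(r) = C_∞ + (1 − C_∞) e^(−r/a).

The reported aggregate size is **2a**, twice the fitted correlation length.
A particle-space union-find over adhesin contacts serves as an independent
cross-check.  Details, unit conventions, and every judgement call are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the three-strain comparison at desk scale (64 cells in a periodic 200³
box, 2×10⁵ τ equilibration, 5 replicate seeds per strain, ~10–15 min on one
CPU):

```python
from piliagg import run_experiment

result = run_experiment(preset="desk", base_seed=1)
print(result.summary.to_string(index=False))
```

```
               strain  mean_size  sd_size  n_ok
   localized_adhesive   9.398036 0.726799     5
   dispersed_adhesive  13.831910 1.875992     5
dispersed_nonadhesive   7.543387 0.378558     5
```

Reading the table: the non-adhesive control's 2a ≈ 7.5 px is the footprint
of isolated cell disks (diameter 10 px) — the no-structure baseline.
One-sided adhesin patches raise the size modestly (≈ 9.4; mostly dimers,
since binding needs patch-to-patch contact), while dispersed adhesins more
than offset the baseline (≈ 13.8; every collision orientation can bind, and
`result.rows["mean_cluster_size"]` shows multi-cell contact clusters), so
dispersed > localized > non-adhesive replicate by replicate.  The same
machinery quantifies real images:

```bash
pili-agg binarize --in micrograph.tif --out mask.png   # adaptive threshold
pili-agg quantify --in mask.png --out size.json        # C(r) fit, 2a
pili-agg experiment --preset desk --seed 1 --out rows.csv
```

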