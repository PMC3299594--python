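# kinaselike

Kinase-likeness scoring and focused-library design from physicochemical
descriptors.

Protein kinases share a conserved ATP-binding cleft, and the ATP-competitive
inhibitors that occupy it cluster in a narrow region of physicochemical
space. `kinaselike` exploits that observation the way Lipinski's rule-of-five
exploits drug-likeness: it scores any small molecule by how closely nine
cheap 2D descriptors — molecular weight (Wt), rotatable bonds (RB), H-bond
acceptors (HBA) and donors (HBD), Wildman–Crippen logP (SlogP), topological
polar surface area (TPSA), ring count (Rings), and nitrogen/oxygen counts
(nN, nO) — match the property distributions of known kinase actives. That
makes it a fast, scaffold-independent filter for prioritizing screening
databases and carving kinase-focused subsets out of them.

## The scores

**KLS (kinase-like score)** of a compound with descriptor vector
*X₁…X₉* under a training profile (μᵢ, σᵢ):

    KLS = Σᵢ exp( −(Xᵢ − μᵢ)² / σᵢ² )

with any descriptor falling outside its P10–P90 training window contributing
exactly 0 (note the σ² denominator — the kernel is deliberately narrower
than a Gaussian density). KLS ranges from 0 to 9; 9 means every descriptor
sits at the kinase-actives mean. The built-in reference profile was trained
on 22,615 kinase actives (Kᵢ or IC₅₀ < 10 μM).

**KLSC** compares whole libraries: it is the mean absolute difference
between two libraries' 9×9 Pearson descriptor-correlation matrices over the
36 unordered descriptor pairs. Lower = more alike; 0 = identical correlation
structure.

**Seeded-ROC evaluation**: spike a random 1% of known actives into a
candidate library, rank everything by KLS, and measure ROC AUC (10 repeats).
AUC ≈ 0.5 means the library is indistinguishable from kinase actives —
i.e. strongly kinase-like; AUC → 1 means it occupies different property
space.

## Worked example

```
$ cat ex.smi
CCN(CC)CCNC(=O)c1c(C)[nH]c(/C=C2\C(=O)Nc3ccc(F)cc32)c1C sunitinib
Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1 imatinib
CC(=O)Oc1ccccc1C(=O)O aspirin

$ kinaselike score --in ex.smi --out scored.csv
$ cut -d, -f1,11 scored.csv
id,kls
sunitinib,7.323345864273481
imatinib,4.908179744607949
aspirin,3.3032337184079488
```

Sunitinib, a marketed ATP-competitive kinase drug, scores 7.3 of 9 — its
descriptors sit close to the kinase-actives means. Imatinib scores lower
(4.9): at 494 Da with 7 nitrogens it drifts toward its profile windows'
edges. Aspirin (3.3) is simply too small and too oxygen-rich to look
kinase-like. The same file's fingerprint diversity:

```
$ kinaselike diversity --in ex.smi
0.9165
```

i.e. the three compounds share almost no Morgan/ECFP_6 substructure bits
(mean pairwise Tanimoto distance 0.92 of a possible 1.0).

The library-level API follows the same shape:

```python
import kinaselike as kl

profile = kl.kbd_reference_profile()          # built-in kinase profile
table   = kl.generate_descriptor_table(       # or your own descriptor CSV
    kl.GeneratorSpec.from_table1("NCI", n=20_000, rng_seed=0))
scored  = kl.score_library(table, profile)
result  = kl.seeding_experiment(scored, actives=..., fraction=0.01,
                                n_repeats=10, rng_seed=7)
print(result.mean_auc)
```

Other subcommands: `fit-profile` (train a profile on any descriptor table),
`evaluate` (seeded-ROC), `build-library` (pool, dedupe, drop known actives,
keep the top-N by KLS), `simulate` (synthetic descriptor tables from
published library statistics, optionally with the reference correlation
structure).

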