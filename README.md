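# seqcerosene

Sequence-level color encoding of macromolecular structures: every residue and
bound compound of a protein/DNA/RNA complex is painted with an RGB color that
encodes its 3D position, so that spatial proximity can be read directly off
the sequence as color similarity — and so that the 3D coordinates can be
decoded back from the colors.

Structure figures (cartoons, surfaces) show geometry but hide the sequence;
plain sequences show order but hide geometry. This tool produces colorized
FASTA-like sequence figures that carry both: residues that sit together in
space share similar colors, anti-parallel partner strands show mirrored color
gradients, and a ligand's color immediately locates it relative to the chains
that bind it. It is aimed at structural bioinformaticians triaging many
structures or models, and at teaching settings where a one-dimensional view
of a fold is easier to annotate than a 3D viewer.

## Method

Each residue is reduced to one representative coordinate `p_i` (by default
the Cβ atom, Cα for glycine; alternatively Cα, the side-chain centroid, or
the terminal heavy side-chain atom; nucleotides and compounds always use
their heavy-atom centroid). For the set *P* of representative coordinates:

1. centroid: `p_c = (1/|P|) Σ p_i`
2. per-axis span: `s_x = max_i |p_i,x − p_c,x|` (likewise `s_y`, `s_z`),
   and `s_max = max(s_x, s_y, s_z)`
3. floor: `s_max ← max(s_max, 23 Å)` — without it, mini-structures would be
   stretched to fill the color cube and read as large
4. color: `c_red = 128·(p_x − p_c,x)/s_max + 128`, likewise green/y and
   blue/z.

Equivalently, the structure is placed in a cube of side `2·s_max` centered
on `p_c` and that cube is rescaled to the RGB cube of side 256. The map is
affine and invertible: `p = (c − 128)/128 · s_max + p_c` recovers every
coordinate exactly from the continuous channels, and to within `s_max/256` Å
per axis from the rounded 8-bit channels.

## Worked example

```sh
python - <<'EOF'
from pathlib import Path
from seqcerosene.fixtures import make_ideal_helix, structure_to_pdb
Path("demo").mkdir(exist_ok=True)
Path("demo/helix30.pdb").write_text(structure_to_pdb(make_ideal_helix(30)))
EOF
seqcerosene run demo/helix30.pdb --formats svg,raw,pml --out demo/out
```

prints

```
processed 1 structure(s): 1 ok, 0 failed
  ok   helix30  s_max=23.00 A (floor applied)  3 artifact(s)
```

A 30-residue ideal helix spans only 21.75 Å along its axis, so the 23 Å
floor fires and the reported effective span is 23.00 Å. The raw table
`demo/out/helix30/helix30.tsv` starts

```
# centroid	0.141033 0.024867 21.750000
# s_max_effective	23.000000
# floor_applied	true
chain_id	author_number	insertion_code	entity	entity_class	R	G	B	c_red	c_green	c_blue
A	1	.	A	polymer_residue	148	128	7	148.362945	127.861612	6.956522
A	2	.	A	polymer_residue	124	149	15	123.542075	148.686655	15.304348
```

Residue 1 sits at the bottom of the helix, far below the structure centroid
in z, hence its near-zero blue channel (6.96); the red/green channels
oscillate with the helical turn. Decoding residue 1's continuous channels
with the header's centroid and span returns its Cβ coordinate:
`(148.362945 − 128)/128 · 23 + 0.141033 = 3.800 Å` on x, and so on per axis.
Alongside the TSV, `helix30.svg` holds the colorized sequence figure and
`helix30.pml` colors the original structure residue-by-residue in PyMOL
(`pymol helix30.pdb helix30.pml`).

`seqcerosene run` also accepts many PDB files or a zip/tar archive in one
call, `--mode {cb,ca,sc-centroid,terminal}` to change the representative
atom, `--include-waters`, and `--wrap` for the figure line width.

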