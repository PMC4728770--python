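# Methods

## The embedding

The package maps each residue/compound of a structure to an RGB color through
an affine, invertible transform of one representative 3D coordinate per
entity. With *P* the set of representative coordinates, the structure
centroid is `p_c = (1/|P|) Σ p_i`; the per-axis span is the maximum absolute
deviation from the centroid, `s_x = max |p_i,x − p_c,x|` (and likewise y, z);
`s_max` is the largest of the three spans, floored at 23 Å; and each point
maps to channels `c = 128·(p − p_c)/s_max + 128` with x→red, y→green,
z→blue. Geometrically the structure is boxed in a cube of side `2·s_max`
centered on the centroid and rescaled to the RGB cube of side 256.

Assumptions worth making explicit:

* **No rotation.** Axes are taken from the deposited coordinates as-is (no
  PCA, no reorientation), so the same complex deposited in two different
  frames yields different colors. Colors are invariant to rigid translation
  and, above the floor, to uniform scaling about the centroid — but not to
  rotation. This is intentional: it keeps the map affine and the decoding
  trivial.
* **One shared frame per structure.** Centroid and spans are computed jointly
  over all chains *and* compounds, so colors are comparable across chains of
  the same structure, and a bound ligand's color locates it relative to the
  chains. Colors are *not* comparable across structures.
* **The span is an L∞ statistic.** A single far-flung atom group (e.g. a
  distant ion kept as a compound) enlarges `s_max` and compresses everything
  else toward mid-gray. Excluding waters by default exists partly for this
  reason.

## Parameters

| parameter | default | meaning |
|---|---|---|
| minimum span | 23 Å | floor on `s_max`; published constant (95th percentile of the span distribution of sub-40-residue structures), not re-derived here |
| representative mode | `cb` | Cβ, Cα for glycine; alternatives `ca`, `sc-centroid`, `terminal` |
| waters | excluded | `--include-waters` reports them as compounds |
| wrap | 60 | residues per figure row (FASTA convention); ruler every 10 |
| raster scale | 2.0 | PNG pixels per SVG unit |

The floor matters for anything smaller than ~46 Å across: below it, colors
compress toward mid-gray in proportion to `s_max_raw/23`, which is exactly
the point — a hexapeptide should not display the same color spread as a
ribosome. `floor_applied` is false at `s_max_raw = 23.0` exactly (the floor
only substitutes when the observed span is smaller).

## Representative coordinates

Amino acids under the default mode use Cβ (glycine: Cα; missing Cβ: Cα,
recorded as `fallback_c_alpha`). The side-chain centroid is the unweighted
mean of heavy atoms outside {N, CA, C, O, OXT}; residues with no side-chain
heavy atoms fall back to Cα. The terminal-heavy mode uses a per-residue-type
lookup of the most distal heavy atom with a fallback path walking back toward
Cα (LYS→NZ, SER→OG, TYR→OH, ...); branch points resolve to the
lexicographically smallest atom name (ASP→OD1, VAL→CG1), except arginine,
which uses CZ, the last unbranched atom before the symmetric guanidinium
fork. Unknown residue types use the side-chain atom farthest from Cα.
Nucleotides and compounds always use the heavy-atom centroid regardless of
mode. Hydrogens never contribute (most deposited files omit them; colors
must not depend on protonation). A residue with no heavy atoms is carried
through as *unmapped*: it appears in the outputs (hatched tile in SVG, `NA`
channels in the raw table) but contributes nothing to the frame and gets no
PyMOL color statement.

## Numerical choices

* **Rounding and the 256 endpoint.** Continuous channels of in-structure
  points lie in [0, 256]; the extreme point on the dominant axis attains 0 or
  256 exactly. 8-bit display channels are rounded half-away-from-zero and
  clamped to [0, 255]. Rounding loses at most half a channel unit, so
  decoding quantized channels recovers coordinates to `s_max/256` Å per axis;
  the clamp affects only the exact value 256 (→255), where the display-color
  error doubles to `s_max/128`. The raw table therefore stores the continuous
  channels to six decimals alongside the 8-bit values, and decoding from the
  raw table is exact to the printed precision. `RGBColor.quantized` exposes
  the rounded-but-unclamped channels for analyses that need the strict
  quantization bound.
* **Altloc resolution** keeps the highest-occupancy conformer per atom name,
  ties broken by smallest altloc character — deterministic and standard.
* **Multi-MODEL files**: first model only; an ensemble has no single set of
  coordinates to color.
* **PML precision**: channel values scaled to [0,1] at three decimals, below
  the 1/255 quantization step, keeping scripts diff-stable.
* **Degenerate inputs**: a single point (or all-coincident points) has zero
  spans; the floor makes the transform well-defined and every color
  mid-gray (128,128,128). Empty structures and all-unmapped structures raise
  explicit errors.

## Synthetic fixtures

Tests run entirely on generated structures, serialized to PDB text and
re-parsed so every stage sees realistic bytes. The generators emulate the
features that exercise the selection and parsing rules — glycines without
Cβ, residues with missing atoms, altloc duplicates, multi-MODEL files,
hydrogen-only residues, waters, ligands, anti-parallel nucleotide strands,
and mini-structures below the 23 Å floor — with deliberately schematic
geometry (collinear chains, ideal helices, rigid strands on a 0.001 Å grid)
chosen so expected embeddings are hand-computable. They do not emulate real
stereochemistry, crystallographic disorder beyond single altloc pairs,
chain breaks, or mmCIF-scale entity bookkeeping; passing tests therefore
validate the transform, its inverses and the artifact formats, not
robustness to every deposited-file dialect. The acceptance checks use a
40-residue random coil (60 Å box) and a two-residue collinear chain with
40 Å span — sizes at which every quantity is analytic.

## Known limitations

* PDB fixed-column input only; no mmCIF, no SEQRES gap reconstruction, no
  assembly expansion.
* Color similarity is necessary but not sufficient for spatial proximity:
  the RGB cube is a rescaled L∞ box, and perceptual color distance is not
  proportional to Euclidean distance (no perceptual-uniformity correction is
  applied, by design — the channels must stay decodable).
* HETATM groups are always compounds; a modified residue deposited as
  HETATM (e.g. MSE) is reported in the compound section rather than inside
  the chain sequence.
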