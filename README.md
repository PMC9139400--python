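# molprint

Convert molecular structures into physically printable 3D meshes.

Molecular 3D printing turns atomic coordinates into tangible teaching and
research objects, but a surface dumped by a molecular viewer is rarely
buildable: printers require *manifold* geometry (every edge shared by
exactly two triangles, normals outward, an unambiguous enclosed volume),
sane wall thicknesses, a scale a hand can hold, and — for models that
assemble, like virus capsids — sockets for the magnets that mimic the
shape/charge complementarity driving the real assembly.

`molprint` covers that pipeline end to end for the three classic printable
representations:

* **CPK (space-filling)** — the union of van-der-Waals spheres, meshed as a
  single watertight solid by contouring the union's signed-distance field
  on a voxel grid (no per-atom sphere tessellation, no internal
  intersecting polygons, no bloated files).
* **Backbone tube** — a natural cubic spline through the CA trace (or
  phosphate trace for nucleic acids) swept with a circular cross-section,
  hemispherically capped, with optional cylindrical **struts** unioned
  between nearby chain segments so the meandering skeleton survives
  handling.
* **Gaussian molecular surface** — the isocontour of a sum of atom-centred
  Gaussians

  $$D(\mathbf{x}) = \sum_i \exp\!\left[\,b\left(\frac{|\mathbf{x}-\mathbf{x}_i|^2}{r_i^2} - 1\right)\right],
  \qquad b < 0,$$

  contoured at isovalue 1, where an isolated atom's level set is exactly its
  van-der-Waals sphere of radius $r_i$. The blobbiness $b$ sets the level of
  detail: $b \to 0^-$ smooths toward a single envelope, large $|b|$ resolves
  atoms.

Around the representations sit the print-preparation tools: manifold
validation and repair, interior hollowing, voxel-based Boolean
subtraction/intersection, thin-wall and cross-layer rod screening per
printer profile, the standard magnification registry (40, 20, 10, 5 and
1 million times actual size, with 1 Å = 10⁻⁷ mm), subunit-interface
detection, magnet-socket carving with complementary polarity, and
exporters for binary/ASCII STL, VRML 2.0 (per-vertex color) and OBJ.

Synthetic builders make everything testable without downloads: peptide
chains placed residue-by-residue from phi/psi/omega dihedrals with ideal
backbone geometry, B-form DNA double-helix traces (3.4 Å rise, 36°/bp
twist), and icosahedral capsids assembled from 12 symmetry placements of a
pentamer, itself 5 rotated copies of a protomer.

## Worked example

```python
import molprint as mp

# an idealized 12-residue alpha helix (phi = -57, psi = -47)
helix = mp.build_peptide_chain(12, mp.TorsionSpec.uniform(12, -57.0, -47.0))
t = mp.measure_torsions(helix)
print(round(t.phi[5], 3), round(t.psi[5], 3))   # -57.0 -47.0

helix = mp.assign_colors(mp.assign_radii(helix))
surface = mp.gaussian_surface(helix, color_by_atom=True)
report = mp.validate_mesh(surface)
print(report.watertight, round(report.signed_volume, 1))  # True 576.6

mm = mp.apply_scale(surface, mp.lookup_scale("individual-protein"))
print(mm.unit, [round(float(x), 1) for x in mm.extents])  # mm [33.8, 29.3, 32.2]
```

A 12-residue helix at the individual-protein scale (20 million ×) is a
comfortable ~3 cm part. The same flow runs from the shell:

```bash
molprint helix12 --rep surface --scale individual-protein --out helix.stl
molprint 1abc.pdb --rep cpk --scale atomic-components --format vrml --out cpk.wrl
molprint capsid --rep capsid --scale large-assembly-virus --sockets --out capsid.stl
```

The capsid invocation writes 12 pentamer meshes with magnet sockets carved
at the detected subunit interfaces, plus a flat key-value manifest
(`*.manifest.txt`) recording mesh statistics, warnings, socket positions
and polarities, and every file written.

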