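# molray

Headless, deterministic molecular visualization and analysis toolkit:

- **Implicit-primitive ray-casting** — van der Waals, solvent-accessible
  surface (true union rendering), sticks and ball-and-sticks are evaluated
  analytically per pixel, no tessellation.
- **Discrete Solvent Excluded Surface** — signed solvent-accessible field on
  a regular grid, Euclidean distance transform, self-contained marching
  cubes with gradient normals; OBJ export.
- **Cartoon ribbons** — centripetal Catmull-Rom splines through the CA
  trace, rotation-minimizing frames, class-dependent cross-sections
  (helix/sheet/coil) with sheet arrowheads; secondary structure from file
  records or a CA-distance heuristic.
- **Deferred rendering pipeline** — G-buffer (depth / view-space normal /
  albedo / object id), flat/matte/glossy/toon shading, seeded SSAO, linear
  fog, outline detection, supersampling anti-aliasing, and background
  compositing with user-defined transparency. Snapshots up to 8K
  (7680x4320), bit-reproducible for a fixed seed.
- **Cameras** — trackball (orbit around a focus) and free-fly.
- **I/O** — PDB (fixed-column, MODEL/CONECT/HELIX/SHEET), mmCIF
  (streaming atom_site reader), DCD trajectories (both endiannesses), PDB
  download by accession with a local cache, PNG and OBJ output.
- **Analysis** — distance/angle/dihedral measurements, Kabsch superposition
  and CE (combinatorial extension) structural alignment.
- **Fixtures** — deterministic generators (ideal helices, extended chains,
  sphere clusters, toy PDB texts, synthetic DCDs) so the entire stack is
  testable offline.

## CLI

```sh
# render a structure to PNG (reps: vdw | sas | sticks | ballstick | cartoon | ses)
molray render input.pdb --rep vdw --color element --width 800 --height 600 \
    --shading glossy --ssao --seed 7 --bg '#00000000' --out out.png

# fetch from the PDB by accession (cached under ~/.cache/molray or $MOLRAY_CACHE)
molray render --fetch 7c4h --rep cartoon --out cartoon.png

# solvent excluded surface to OBJ; prints the mesh area in A^2
molray ses input.pdb --probe 1.4 --spacing 0.4 --out surface.obj

# measurements (atom specifier: CHAIN/RESI/NAME)
molray measure distance input.pdb A/1/N A/2/CA
molray measure dihedral input.pdb A/1/N A/1/CA A/1/C A/2/N

# CE structural alignment: prints aligned_length, RMSD and the 3x4 transform
molray align a.pdb b.pdb --chain-a A --chain-b A
```

Exit codes: 0 success, 1 I/O or parse failure, 2 invalid arguments.

## Library quick start

```python
import molray
from molray.fixtures import make_ideal_helix

system = molray.assign_radii(molray.MoleculeSystem(atoms=...))  # or io readers
mesh = molray.compute_ses(system, probe_radius=1.4, spacing=0.4)

scene = molray.Scene(spheres=molray.build_vdw(system))
from molray.render import frame_scene
camera = frame_scene(scene)
image = molray.render_snapshot(scene, camera, molray.RenderSettings(), 800, 600)
```

Sessions (structures, camera, render settings, measurements) round-trip
through versioned JSON via `molray.save_session` / `molray.load_session`.

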