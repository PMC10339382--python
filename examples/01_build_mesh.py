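"""Build the layered tooth cross-section mesh and summarize it.

The mesh is a plane-strain slice through a transplanted tooth: a dentin
shell around the root canal, a 200 µm periodontal ligament, alveolar bone
out to the fixed outer boundary, and a crown block carrying the load edge.
"""

from toothmor import GeometrySpec, build_toy_mesh, mesh_summary, write_vtk

spec = GeometrySpec()  # 1.2 mm root half-width, 0.2 mm ligament, 0.1 mm elements
mesh = build_toy_mesh(spec)

print(mesh_summary(mesh).to_string(index=False))
write_vtk("mesh.vtk", mesh)
print("\nwrote mesh.vtk (legacy VTK ASCII; region tag stored as cell data)")
print("Counts show every tissue layer is meshed; the ligament ring has at "
      "least one element through its 0.2 mm thickness.")
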