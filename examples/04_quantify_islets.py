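"""3-D islet reconstruction and volume quantification from truth masks.

Per-slice connected components are stitched across neighbouring slices
whenever their centroids lie within gamma = 5 px, then volumes follow
from voxel counts at 7.8 um pitch.  On phantom truth masks the recovery
is exact: counts and volumes equal the generator's manifest.
"""

from isletseg import PhantomSpec, generate_phantom, quantify_stack
from isletseg.quantify import count_islets_above, size_distribution

spec = PhantomSpec(stack_shape=(48, 224, 224), n_islets=10, seed=3)
_, mask, manifest = generate_phantom(spec)

islets = quantify_stack(mask, gamma=5.0, pitch_um=7.8)
print(f"true islets: {manifest.n_islets}, recovered: {len(islets)}")

recovered = sorted(i.volume_um3 for i in islets)
truth = sorted(i["volume_um3"] for i in manifest.islets)
exact = sum(abs(a - b) < 1e-9 for a, b in zip(recovered, truth))
print(f"volumes recovered exactly: {exact}/{len(truth)}")

dist = size_distribution(islets, [0, 25e3, 100e3, 500e3, 1500e3])
for lo, hi, n in zip(dist.bin_edges[:-1], dist.bin_edges[1:], dist.counts):
    print(f"  {lo/1e3:7.0f}-{hi/1e3:7.0f} x10^3 um^3: {n} islets")
print(f"  >= 1500 x10^3 um^3: {count_islets_above(islets, 1500e3)} islets")
# The histogram is the size distribution used to compare healthy vs
# diabetic cohorts; large islets are the class reported most sensitive.
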