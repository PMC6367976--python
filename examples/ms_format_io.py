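"""Read and write ms-style simulator output.

Shows the round trip between the text dialect used by ms-family coalescent
simulators and the in-memory alignment container, and how an alignment
becomes a fixed-shape network input.
"""

import numpy as np

from coalcnn import imageprep, msio, simgen

# simulate a small sample and serialize it as ms text
aln = simgen.simulate_alignment(
    simgen.ConstantThetaScenario(theta=8.0), n_chroms=6, seed=11)
text = msio.write_ms([aln])
print("ms-dialect text for one replicate:")
print("\n".join(text.splitlines()[:8]) + "\n...")

back = msio.read_ms(text)[0]
assert (back.alleles == aln.alleles).all()
print(f"\nround trip exact: {back.n_chroms} chromosomes x {back.n_sites} sites")

# prepare it for a network: encode, sort, pad, transpose
encoded = imageprep.encode_alleles(back.alleles, imageprep.Encoding.ZERO_ONE)
image, positions = imageprep.pad_and_shape(
    encoded, back.positions, width_W=back.n_sites + 4, sort=True, transpose=True)
print(f"network input: {image.pixels.shape} (sites x chromosomes), "
      f"{image.width_W - image.n_real_sites} padded site rows,")
print(f"positions padded with {positions.pad_value}: {positions.values[-5:]}")
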