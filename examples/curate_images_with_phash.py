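"""Curate an image pool with perceptual hashing.

Builds 12 textured test images of which two are near-duplicates of earlier
ones, removes the near-duplicates by Hamming distance between 64-bit DCT
hashes, and keeps the most mutually dissimilar 60% of the survivors.
"""

from wildtrack.augmentation import filter_similar, hamming, phash
from wildtrack.synthetic import generate_test_images

images = generate_test_images(12, size=64, seed=11, n_duplicates=2)

sigs = [phash(im) for im in images]
print("Hamming distance of duplicate 10 to its source 0:", hamming(sigs[10], sigs[0]))
print("Hamming distance of two distinct textures (0 vs 1):", hamming(sigs[0], sigs[1]))

kept = filter_similar(images, keep_fraction=0.6, dup_threshold=5)
print("kept indices:", kept)
print(
    f"\n{len(kept)} of 12 images survive: the two noisy copies fall to the "
    "duplicate rule (distance <= 5), and the top 60% most dissimilar of the "
    "10 survivors are retained for downstream compositing."
)
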