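"""Build an LSA semantic space from a token corpus and compare words.

Trains embeddings on the bundled synthetic reference corpus (co-occurrence
counts over 5-gram windows -> log(count+1) -> truncated SVD -> unit
vectors) and prints a few cosine similarities: same-topic words should sit
much closer than cross-topic ones.
"""

import qcla

config = qcla.GeneratorConfig()
tokens = qcla.generate_reference_corpus(config, seed=1)
space = qcla.build_space(tokens, d=512)  # capped at the matrix size and logged

print(f"vocabulary: {len(space)} words, {space.dimensionality} dimensions\n")
pairs = [
    ("sad", "hopeless"),      # same topic (depression)
    ("nervous", "uneasy"),    # same topic (anxiety)
    ("sad", "rent"),          # cross topic
    ("nervous", "job"),       # cross topic
]
for a, b in pairs:
    sim = qcla.cosine(space.vector(a), space.vector(b))
    print(f"cosine({a!r}, {b!r}) = {sim:+.3f}")

resp = qcla.encode_response(space, ["sad", "tired", "hopeless"])
print(f"\nresponse vector from 3 words: unit norm, {resp.n_known_words} known words")
print("cosine(response, 'gloomy') =", round(qcla.cosine(resp, space.vector("gloomy")), 3))
# Expect ~+0.95 within a topic and markedly lower across topics (the
# neutral glue vocabulary keeps everything mildly positive): the space has
# learned the corpus's co-occurrence structure.
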