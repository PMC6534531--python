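import random

from bmgraph.fixtures import RandomTreeSpec, random_colored_tree


def iter_random_trees(count, max_leaves=20, colors=(2, 4), seed0=0, min_leaves=2):
    """Deterministic stream of random leaf-colored trees for property tests."""
    rng = random.Random(seed0)
    for i in range(count):
        n = rng.randint(min_leaves, max_leaves)
        k = rng.randint(colors[0], min(colors[1], n))
        yield random_colored_tree(RandomTreeSpec(n, k, seed=seed0 * 10_000 + i))
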