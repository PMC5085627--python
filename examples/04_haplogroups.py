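"""Haplogroup assignment by path scoring on the bundled tree.

A sample carrying the defining variants of the B4a path (plus private
variants) scores 1.0 at B4a; dropping one defining variant lowers the score
but keeps the assignment on the correct branch.
"""

from mitovar import assign_haplogroup, bundled_tree

tree = bundled_tree()
path = tree.path_variants("B4a")
print("B4a path variants:", ", ".join(path))

full = assign_haplogroup(set(path) | {"G9999A"}, tree, "full")
print(f"full path + private -> {full.haplogroup} (score {full.score:.2f}, "
      f"runner-up {full.runner_up})")

partial = assign_haplogroup(set(path[:-1]), tree, "partial")
print(f"one defining variant missing -> {partial.haplogroup} "
      f"(matched {partial.matched}/{partial.expected})")
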