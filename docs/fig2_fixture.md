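# The worked-example fixture DAG

Synthetic BP sub-DAG for the term pair GO:0044260 / GO:0006139. Only
the path node ICs and path lengths of the worked example are fixed by
the published figure; this is the minimal topology consistent with all
of them. IC values in parentheses are injected, not computed; the two
starred values are synthetic choices that preserve the published path
selection (see below).

```
                      GO:0008150  biological_process        (0.0, root)
                       /        \
        GO:0008152 (1.098)    GO:0009987 (0.407)
            /        \            |
 GO:0071704 (1.255)  GO:0044237 (1.329)
    /       \          /      |      \
GO:0043170 GO:1901360 GO:0034641 GO:0006807*  |
 (2.086)    (1.479)    (1.999)   (1.555*)     |
    \          \        |        /            |
     \          \       |       /             |
   GO:0044260 (2.158)   |      /         GO:0006139 (1.617)
      |__________________|____/               |
      (3 parents: 0043170, 0034641, 0006807)  (2 parents: 1901360, 0044237)
```

Edges (child → parent, all `is_a`):

| child      | parents                              |
|------------|--------------------------------------|
| GO:0008152 | GO:0008150                           |
| GO:0009987 | GO:0008150                           |
| GO:0071704 | GO:0008152                           |
| GO:0044237 | GO:0008152, GO:0009987               |
| GO:0043170 | GO:0071704                           |
| GO:1901360 | GO:0071704                           |
| GO:0034641 | GO:0044237                           |
| GO:0006807 | GO:0044237                           |
| GO:0044260 | GO:0043170, GO:0034641, GO:0006807   |
| GO:0006139 | GO:1901360, GO:0044237               |

Reproduced published quantities:

* DisComAnc(GO:0044260, GO:0006139) = {GO:0071704, GO:0044237} — the
  only minimal common ancestors.
* Branch GO:0071704: unique combined path
  GO:0044260 → GO:0043170 → GO:0071704 ← GO:1901360 ← GO:0006139 with
  node ICs {2.158, 2.086, 1.255, 1.479, 1.617} and 4 edges; unique root
  path with ICs {1.255, 1.098} and 2 edges.
* Branch GO:0044237: two combined paths (via GO:0034641 and via
  GO:0006807) and two root paths (via GO:0008152 and via GO:0009987).
  IIC selection picks the combined path with ICs
  {2.158, 1.999, 1.329, 1.617} (3 edges) and the root path with ICs
  {1.329, 0.407} (2 edges), matching the published choice.

Synthetic choices: GO:0006807's IC (1.555*) must only be below 1.999 so
the minimum-IIC selection prefers the published alternative; the edge
GO:0044237 → GO:0008152 realises the published *second* root path, whose
interior IC is not printed — routing it through the IC-1.098 node keeps
the DAG minimal and leaves the published maximum-IIC choice
({1.329, 0.407}) strictly preferred.
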