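# data/

Optional published model files used by the walkthrough acceptance tests
(`tests/test_acceptance.py`). They are distributed as supplementary material
of the original publication and are not shipped here. To run the
walkthroughs, place:

- `flavonoid_demo.xml` — the 137-metabolite × 117-reaction flavonoid
  demonstration network (SBML),
- `arabidopsis.xml` — the 1348-metabolite × 1468-reaction *Arabidopsis
  thaliana* genome-scale network (SBML),
- `external_metabolites.txt` — the a-priori external-metabolite list, one
  identifier per line, `#` comments.

All other tests generate their inputs programmatically.
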