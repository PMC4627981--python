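# Packaged demonstration data

`demo_units.csv` — 40 treatment units (83 vegetation patches) in long form:
one row per (unit, EVC) with area (ha) and stand age (years).  Unit totals
fall in a 23-29 ha band; total treatable area R = 1038.77 ha.

`demo_evc.csv` — the 40-row EVC catalogue: minimum/maximum Tolerable Fire
Interval (years) and fuel-type key per class.

Transcription provenance: both tables were recovered from a flattened
four-column typeset layout.  The reading was reconstructed under the
constraints that every EVC code resolves in the catalogue, unit ids form
non-decreasing runs down the table columns (units 298 and 813 span column
boundaries), and exactly 40 distinct units exist; residual digit-split
ambiguities (27 of 83 patch rows) were closed by requiring unit totals in
the 23-29 ha band shown by every unambiguous unit, which left exactly one
reading per row.

Two catalogue rows remain ambiguous in the source and are flagged here:

* EVC 894 (Scoria cone woodland): read as min 4 / max 15 / fuel 7,
  matching the adjacent grassy-woodland rows (EVCs 55, 67) and the
  catalogue's area-percentage column.
* EVC 31 (Cool temperate rainforest): read as min 45 / max 999 / fuel 1;
  the 999 is taken as a no-burn sentinel.

Neither EVC occurs in `demo_units.csv`.

Fuel curves are deliberately NOT packaged: numeric accumulation data are
unpublished for this landscape.  Use `burnplan.synth.default_fuel_curves()`
(a documented parametric substitution) or supply your own `curves.csv`.
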