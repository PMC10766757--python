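note: Mapping of the printed grid values/rotations of the observed big-triangle
  frequency table (Monk, initial phase) onto this package's Monk anchor-grid numbering
  and rotation convention. The published text locates the modal error at printed
  location 17 while the printed table's 47.5% row reads grid 13, rotation 270; the
  table is preserved as printed and its 47.5% row is mapped to the modal wrong big-triangle
  placement (hypotenuse along the belly base). The two correct belly placements
  carry the 10% rows.
mapping:
- table:
  - 7
  - 45
  placement:
  - big_triangle
  - 1
  - 90
  - false
- table:
  - 7
  - 90
  placement:
  - big_triangle
  - 2
  - 90
  - false
- table:
  - 8
  - 90
  placement:
  - big_triangle
  - 2
  - 225
  - false
- table:
  - 8
  - 270
  placement:
  - big_triangle
  - 3
  - 90
  - false
- table:
  - 9
  - 180
  placement:
  - big_triangle
  - 3
  - 225
  - false
- table:
  - 10
  - 225
  placement:
  - big_triangle
  - 4
  - 90
  - false
- table:
  - 12
  - 45
  placement:
  - big_triangle
  - 4
  - 225
  - false
- table:
  - 12
  - 135
  placement:
  - big_triangle
  - 13
  - 0
  - false
- table:
  - 12
  - 180
  placement:
  - big_triangle
  - 5
  - 90
  - false
- table:
  - 13
  - 270
  placement:
  - big_triangle
  - 1
  - 225
  - false
- table:
  - 14
  - 90
  placement:
  - big_triangle
  - 5
  - 225
  - false
- table:
  - 14
  - 180
  placement:
  - big_triangle
  - 6
  - 90
  - false
- table:
  - 17
  - 135
  placement:
  - big_triangle
  - 6
  - 225
  - false
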