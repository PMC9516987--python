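# Strengths and Difficulties Questionnaire item -> domain mapping
# (teacher-completed form; the 2-4 and 4-16 year variants share this layout,
# differing only in item wording). Items are numbered 1-25; responses are on
# a 0/1/2 Likert scale. "reversed" items score 2 - response so that higher
# always means more difficulty (or, for prosocial, less prosocial behaviour).
domains:
  emotional: [3, 8, 13, 16, 24]
  conduct: [5, 7, 12, 18, 22]
  hyperactivity: [2, 10, 15, 21, 25]
  peer: [6, 11, 14, 19, 23]
  prosocial: [1, 4, 9, 17, 20]
reversed: [7, 11, 14, 21, 25]
# domains contributing to the total difficulties score (prosocial excluded)
difficulty_domains: [emotional, conduct, hyperactivity, peer]
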