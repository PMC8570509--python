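landform_grade,human_impact,geodiversity,biodiversity,value
I,None,High,High,I
I,None,Low,High,I
I,None,Low,Low,II
I,Moderate,Middle,Middle,II
I,High,Low,Low,III
II,None,High,High,I
II,None,Low,High,II
II,None,Low,Low,III
II,Moderate,Middle,Middle,II
II,High,Low,Low,III
III,None,High,High,I
III,Moderate,Middle,Middle,III
III,High,Low,Low,III
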