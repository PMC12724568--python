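rpl18a
rps16
rplp2l
rps13
rps17
rpl34
rpl13
rplp0
rpl36a
rpl12
rpl7a
rpl19
rps2
rps15a
rpl3
rpl27
rpl23
rps11
rps27a
rpl5b
rplp2
rps26l
rps10
rpl5a
rps28
rps8a
rpl7
rpl37
rpl24
rpl9
rps3a
rps6
rpl8
rpl31
rpl18
rps27.2
rps19
rps9
rpl28
rps7
rpl7l1
rps29
rpl6
rps8b
rpl10a
rpl13a
rpl39
rpl26
rps24
rps3
rpl4
rpl35a
rpl38
rplp1
rps27.1
rpl15
rps18
rpl30
rpl11
rpl14
rps5
rps21
rpl10
rps26
rps12
rpl35
rpl17
rpl23a
rps14
rpl29
rps15
rpl22
rps23
rps25
rpl21
rpl22l1
rpl36
rpl32
rps27l
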