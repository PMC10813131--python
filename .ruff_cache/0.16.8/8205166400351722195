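/root/pkg/src/plvnetrecording.pyvalidation.pymontage.py__init__.pypreprocess.pyconnectivity.pypipeline.py                                       stats.py�9�,�R��k?��         �   ����I�2��
�q�k?��         �   ������C��k?��         atlas.py-�ܾ'�2�k?��         �   2���l��L�k?��         bands.py�x���6�k?��         cli.py�������q�فk?��         �   ����>@��G�tH�k?��          synth.pyD�_�7�)�k?��         �   }����/��eĹ��k?��         �   P����R�!�ńk?��         graph.py�d���Dx�k?��         �   ������?5A�k?��         ~66D7:+Iz7A�~66D7:+Iz7A���� �   ��������      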